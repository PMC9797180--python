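"""Optional heatmap rendering of the CV and CCC matrices.

The CSV matrices are the authoritative outputs; these plots mirror them
with the decision thresholds as color breakpoints (CV below 10% and CCC
above 0.85 highlighted).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def render_cv_heatmap(cv_matrix: pd.DataFrame, path: str | Path, cv_threshold: float = 10.0) -> None:
    """Features x patients CV map; cells below the threshold stand out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = cv_matrix.to_numpy(dtype=float)
    flagged = np.where(np.isfinite(data) & (data < cv_threshold), 1.0, 0.0)
    fig, ax = plt.subplots(figsize=(max(4, data.shape[1] * 0.4), max(6, data.shape[0] * 0.08)))
    ax.imshow(flagged, aspect="auto", cmap="Purples", vmin=0, vmax=1)
    ax.set_xlabel("patient")
    ax.set_ylabel("feature")
    ax.set_title(f"CV < {cv_threshold:g}% (highlighted)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_ccc_heatmap(ccc_panel: pd.DataFrame, path: str | Path, ccc_threshold: float = 0.85) -> None:
    """Features x (pair, patient) CCC map; cells above the threshold stand out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = ccc_panel.to_numpy(dtype=float)
    flagged = np.where(np.isfinite(data) & (data > ccc_threshold), 1.0, 0.0)
    fig, ax = plt.subplots(figsize=(max(6, data.shape[1] * 0.25), max(6, data.shape[0] * 0.08)))
    ax.imshow(flagged, aspect="auto", cmap="Reds", vmin=0, vmax=1)
    ax.set_xlabel("tissue pair x patient")
    ax.set_ylabel("feature")
    ax.set_title(f"CCC > {ccc_threshold:g} (highlighted)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
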