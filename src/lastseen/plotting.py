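"""Optional rendering helpers (matplotlib): CSVs are the product, plots a view."""

from __future__ import annotations

import pandas as pd


def plot_curves(table: pd.DataFrame, kind: str = "hazard", ax=None):
    """Plot real (blue) vs reported (red) survivorship or hazard curves.

    ``table`` is a curve table as produced by :func:`lastseen.curve_table`
    or read back from its CSV export.
    """
    import matplotlib.pyplot as plt

    if kind not in ("hazard", "survival", "pdf"):
        raise ValueError("kind must be 'hazard', 'survival' or 'pdf'")
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["age"], table[f"real_{kind}"], color="tab:blue", label="real lifespan")
    ax.plot(table["age"], table[f"reported_{kind}"], color="tab:red", label="reported lifespan")
    ax.set_xlabel("age since onset of senescence")
    ax.set_ylabel({"hazard": "mortality risk", "survival": "survivorship", "pdf": "density"}[kind])
    ax.legend()
    return ax


def plot_sweep(table: pd.DataFrame, ax=None):
    """Plot fitted versus true aging parameter from a sweep table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(table["true_value"], table["est_param2"], s=8, color="tab:red", label="naive fit to reported")
    lo, hi = table["true_value"].min(), table["true_value"].max()
    ax.plot([lo, hi], [lo, hi], color="grey", lw=1, label="identity")
    ax.set_xlabel("true aging parameter")
    ax.set_ylabel("fitted aging parameter")
    ax.legend()
    return ax
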