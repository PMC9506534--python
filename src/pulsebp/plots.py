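"""Optional matplotlib renderings of the attribution exports."""

from __future__ import annotations

import numpy as np

from .interpretation import ImportanceReport, ShapMatrix, beeswarm_export


def importance_bar(report: ImportanceReport, ax=None, top_k: int = 15):
    """Horizontal bar chart of mean |attribution| per feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * top_k + 1))
    ser = report.importances.iloc[:top_k][::-1]
    ax.barh(ser.index, ser.values, color="#1f77b4")
    ax.set_xlabel("mean |attribution| (mmHg)")
    ax.set_title("Global feature importance")
    return ax


def beeswarm(shap: ShapMatrix, ax=None, top_k: int = 9, rng_seed: int = 0):
    """Beeswarm-style scatter: attribution vs feature row, colored by
    the feature value's normalized rank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * (top_k + 1) + 1))
    table = beeswarm_export(shap, top_k=top_k)
    rows = list(dict.fromkeys(table["feature"]))
    rng = np.random.default_rng(rng_seed)
    for i, feat in enumerate(rows):
        sub = table[table["feature"] == feat]
        jitter = rng.normal(0, 0.08, size=len(sub))
        color = sub["feature_value_rank"].fillna(0.5)
        ax.scatter(sub["shap_value"], np.full(len(sub), i) + jitter,
                   c=color, cmap="coolwarm", s=8, vmin=0, vmax=1)
    ax.set_yticks(range(len(rows)), rows)
    ax.invert_yaxis()
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("attribution (mmHg)")
    return ax


def dependence(table, rho: float | None = None, ax=None, feature: str = ""):
    """Scatter of attribution vs feature value for one feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["feature_value"], table["shap_value"], s=8, alpha=0.6)
    ax.set_xlabel(f"{feature} value")
    ax.set_ylabel("attribution (mmHg)")
    if rho is not None and np.isfinite(rho):
        ax.set_title(f"{feature}: rank correlation {rho:.2f}")
    return ax
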