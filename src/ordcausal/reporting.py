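"""Rendering of simulation and effect tables, plus run manifests.

Formatting is presentation-only: CSV outputs keep full float precision so
a written-then-read report reproduces the in-memory one exactly, while
markdown rendering rounds to the printed precision (3 decimals for bias
metrics, 2 for odds ratios) and flags |ARebias| >= 5% in bold.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = [
    "render_results_table",
    "render_effect_table",
    "write_manifest",
]

AREBIAS_FLAG = 0.05


def render_results_table(report: pd.DataFrame, fmt: str = "csv") -> str:
    """Render a Monte-Carlo report (long format, one row per cell and
    method) ordered by (scenario, n, beta, gamma, method)."""
    if report.empty or "method" not in report.columns:
        raise ValueError("report must be non-empty with a method column")
    if fmt not in ("csv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    out = report.sort_values(
        ["scenario", "n", "beta", "gamma", "method"]
    ).reset_index(drop=True)
    out["flag"] = out["arebias"].abs() >= AREBIAS_FLAG
    if fmt == "csv":
        return out.to_csv(index=False)
    disp = out.copy()
    for col in ("arebias", "arebias_se", "mse"):
        disp[col] = disp[col].map(lambda v: f"{v:.3f}")
    disp["arebias"] = [
        f"**{a} ({s})**" if f else f"{a} ({s})"
        for a, s, f in zip(disp["arebias"], disp["arebias_se"], disp["flag"])
    ]
    disp = disp.drop(columns=["arebias_se", "flag"])
    return disp.to_markdown(index=False)


def render_effect_table(effects: pd.DataFrame, fmt: str = "csv") -> str:
    """Render an effect table (columns method, or, ci_low, ci_high).

    Markdown cells read "OR (lo-hi)" to 2 decimals with a ``*`` marker
    when the CI strictly excludes 1.
    """
    required = {"method", "or", "ci_low", "ci_high"}
    if effects.empty or not required <= set(effects.columns):
        raise ValueError(f"effect table needs columns {sorted(required)}")
    present = set(effects["method"])
    if not present >= set("ABCD"):
        raise ValueError("methods A-D must all be present")
    if fmt == "csv":
        out = effects.copy()
        out["significant"] = (out["ci_low"] > 1) | (out["ci_high"] < 1)
        return out.to_csv(index=False)
    if fmt != "markdown":
        raise ValueError(f"unknown format {fmt!r}")
    disp = effects.copy()
    mark = (disp["ci_low"] > 1) | (disp["ci_high"] < 1)
    disp["OR (95% CI)"] = [
        f"{o:.2f}{'*' if s else ''} ({lo:.2f}-{hi:.2f})"
        for o, lo, hi, s in zip(disp["or"], disp["ci_low"],
                                disp["ci_high"], mark)
    ]
    keep = [c for c in ("outcome", "method", "term", "OR (95% CI)")
            if c in disp.columns]
    return disp[keep].to_markdown(index=False)


def write_manifest(path: str | Path, config: dict, seed,
                   n_failures: int | None = None) -> Path:
    """Write a JSON reproducibility manifest next to an output file."""
    from . import __version__

    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "package": {"name": "ordcausal", "version": __version__},
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
    }
    if n_failures is not None:
        manifest["n_failures"] = n_failures
    path = Path(path)
    out = path.with_suffix(path.suffix + ".manifest.json")
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out
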