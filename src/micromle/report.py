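"""Report assembly: fit summaries and fitted-density curve tables.

The density table is the headless counterpart of the distribution plot a
bench user expects: an evenly spaced grid of log10 concentration vs. the
fitted normal density over mu +/- 4 sigma, with extra rows flagging the
mean, the LOQ, and the 5th/95th percentiles of the fitted distribution.
Image rendering is left to the caller (any plotting library can consume
the table); the core stays testable without a display.
"""

from __future__ import annotations

import datetime
import hashlib
import math
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import EnumerationDataset, censored_fraction
from .estimator import FitResult
from .likelihood import LognormalParams, log_density

__all__ = ["render_density_table", "build_report", "format_text_report"]

SCHEMA_VERSION = 1


def render_density_table(fit: FitResult, grid_points: int = 201) -> pd.DataFrame:
    """Fitted-density curve over mu +/- 4 sigma with marker rows.

    Columns: ``log10_concentration`` (log10 CFU/g), ``density`` (normal
    density on the log10 scale) and ``marker`` (one of ``""``, ``mean``,
    ``loq``, ``p05``, ``p95``).  Marker rows are inserted at their exact
    positions, so the LOQ row may fall outside the +/- 4 sigma span.
    """
    if not fit.converged:
        raise ValueError("density table requires a converged fit")
    params = fit.params
    if params.sigma <= 0:
        raise ValueError("density table requires sigma > 0")
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    mu, sig = params.mu, params.sigma
    grid = np.linspace(mu - 4 * sig, mu + 4 * sig, grid_points)
    markers = {"mean": mu, "loq": fit.loq_log10,
               "p05": fit.percentile_05, "p95": fit.percentile_95}
    # a grid point falling exactly on a marker would duplicate its row
    grid = grid[~np.isin(grid, list(markers.values()))]
    frames = [pd.DataFrame({"log10_concentration": grid, "marker": ""})]
    frames.append(pd.DataFrame({"log10_concentration": list(markers.values()),
                                "marker": list(markers.keys())}))
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values("log10_concentration", kind="stable",
                              ignore_index=True)
    table["density"] = np.exp(log_density(table["log10_concentration"].to_numpy(),
                                          params))
    return table[["log10_concentration", "density", "marker"]]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_report(dataset: EnumerationDataset, fit: FitResult,
                 source: str | Path | None = None) -> dict:
    """Machine-readable key/value report for one run (schema-versioned)."""
    frac = censored_fraction(dataset)
    return {
        "schema_version": SCHEMA_VERSION,
        "tool": {"name": "micromle", "version": __version__},
        "generated_at": datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds"),
        "input": {
            "path": str(source) if source is not None else None,
            "sha256": _sha256(source) if source is not None else None,
            "mode": dataset.mode,
            "label": dataset.label,
        },
        "data": {
            "n_detected": dataset.n_detected,
            "m_censored": dataset.m_censored,
            "total": dataset.total_weight,
            "censored_percent": round(100.0 * float(frac), 1),
            "loq_cfu_per_g": dataset.loq,
            "loq_log10": dataset.loq_log10,
        },
        "fit": {
            "mean_log10": fit.params.mu,
            "sd_log10": fit.params.sigma,
            "se_mean": fit.se_mu,
            "se_sd": fit.se_sigma,
            "ci95_mean": list(fit.ci95_mu) if fit.ci95_mu else None,
            "ci95_sd": list(fit.ci95_sigma) if fit.ci95_sigma else None,
            "percentile_05": fit.percentile_05,
            "percentile_95": fit.percentile_95,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "message": fit.message,
        },
    }


def _num(x: float | None, nd: int = 2) -> str:
    return "n/a" if x is None else f"{x:.{nd}f}"


def _ci(ci: list | tuple | None) -> str:
    if not ci:
        return "n/a"
    return f"[{ci[0]:.2f}, {ci[1]:.2f}]"


def format_text_report(report: dict) -> str:
    """Human-readable rendering; numbers match the machine report after
    rounding (log-scale estimates to 2 decimals, percentages to 1)."""
    d, f, inp = report["data"], report["fit"], report["input"]
    lines = [
        "Censored lognormal MLE fit (micromle)",
        "=" * 39,
        f"input:          {inp['path'] or '(in-memory)'}",
        f"label:          {inp['label'] or '-'}",
        f"mode:           {inp['mode']}",
        f"samples:        {d['total']} total = {d['n_detected']} quantified "
        f"+ {d['m_censored']} ND",
        f"censored:       {d['censored_percent']:.1f} %",
        f"LOQ:            {d['loq_cfu_per_g']:g} CFU/g "
        f"({d['loq_log10']:.2f} log CFU/g)",
        "",
        f"mean:           {_num(f['mean_log10'])} log CFU/g   "
        f"95% CI {_ci(f['ci95_mean'])}",
        f"SD:             {_num(f['sd_log10'])} log CFU/g   "
        f"95% CI {_ci(f['ci95_sd'])}",
        f"5th percentile: {_num(f['percentile_05'])} log CFU/g",
        f"95th percentile:{_num(f['percentile_95'])} log CFU/g",
        f"log-likelihood: {f['loglik']:.4f}" if math.isfinite(f["loglik"])
        else "log-likelihood: degenerate",
        f"converged:      {f['converged']}",
    ]
    if inp["mode"] in ("QN_1", "QN_2") and d["m_censored"] == 0:
        lines.append("note:           no censored data; "
                     "direct summary (MLE not required)" if inp["mode"] == "QN_1"
                     else "note:           no censored data; interval MLE only")
    if f["message"]:
        lines.append(f"note:           {f['message']}")
    return "\n".join(lines) + "\n"
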