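"""Report generation: CSV/JSON result files and figures.

The report layer performs no arithmetic beyond rounding for display —
every number it writes comes from a result object computed elsewhere.
Currency is written as integer 2024 USD; internal precision is preserved
in the JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

from . import __version__
from .analysis import StrategyResult, incremental_table
from .engine import Strategy
from .uncertainty import PSAResult

__all__ = ["run_manifest", "run_report"]


def _sha256(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_manifest(config_path=None, life_table_path=None, seed=None,
                 perspective: str = "societal") -> dict:
    """Provenance manifest: input hashes, seed, code version, timestamp.
    Re-running with an identical manifest (timestamp aside) reproduces
    byte-identical numeric outputs."""
    return {
        "config_sha256": _sha256(config_path),
        "life_table_sha256": _sha256(life_table_path),
        "seed": seed,
        "perspective": perspective,
        "code_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }


def _table3(results_by_perspective: dict[str, dict[Strategy,
                                                   StrategyResult]],
            wtp: float) -> pd.DataFrame:
    rows = []
    for perspective, results in results_by_perspective.items():
        inc = incremental_table(results, Strategy.UC, wtp, perspective)
        for strat, res in results.items():
            rows.append({
                "perspective": perspective,
                "strategy": strat.value,
                "discounted_life_years": round(res.life_years, 2),
                "discounted_qalys": round(res.qalys, 2),
                "discounted_cost_usd": int(round(res.cost(perspective))),
                "incremental_qalys": (
                    "" if strat is Strategy.UC
                    else round(inc.loc[strat.value, "incr_qalys"], 2)),
                "incremental_cost_usd": (
                    "" if strat is Strategy.UC
                    else int(round(inc.loc[strat.value, "incr_cost"]))),
                "label": inc.loc[strat.value, "label"],
            })
    return pd.DataFrame(rows)


def run_report(out_dir: str | Path,
               results_by_perspective: dict[str, dict[Strategy,
                                                      StrategyResult]],
               wtp: float = 100_000.0,
               tornado_df: pd.DataFrame | None = None,
               psa_result: PSAResult | None = None,
               ceac_df: pd.DataFrame | None = None,
               manifest: dict | None = None) -> dict[str, Path]:
    """Write the result files (and figures where the inputs exist).

    Base-case-only calls simply omit the sensitivity sections.  Returns
    the mapping of artifact name to written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable") from exc

    written: dict[str, Path] = {}

    t3 = _table3(results_by_perspective, wtp)
    written["table3"] = out_dir / "table3.csv"
    t3.to_csv(written["table3"], index=False)

    inc_frames = []
    for perspective, results in results_by_perspective.items():
        inc = incremental_table(results, Strategy.UC, wtp, perspective)
        inc.insert(0, "perspective", perspective)
        inc_frames.append(inc.reset_index())
    written["incremental"] = out_dir / "incremental.csv"
    pd.concat(inc_frames).to_csv(written["incremental"], index=False)

    summary = {
        "wtp": wtp,
        "results": {
            perspective: {s.value: r.to_dict() for s, r in results.items()}
            for perspective, results in results_by_perspective.items()
        },
    }

    if tornado_df is not None:
        written["tornado"] = out_dir / "tornado.csv"
        tornado_df.to_csv(written["tornado"], index=False)
        written["tornado_plot"] = out_dir / "tornado.png"
        _plot_tornado(tornado_df, written["tornado_plot"])

    if psa_result is not None:
        written["psa_draws"] = out_dir / "psa_draws.csv"
        psa_result.draws.to_csv(written["psa_draws"], index=False)
        written["ce_plane_plot"] = out_dir / "ce_plane.png"
        _plot_ce_plane(psa_result, written["ce_plane_plot"])
        summary["psa"] = {"n_draws": psa_result.n_draws,
                          "seed": psa_result.seed,
                          "redraw_count": psa_result.redraw_count}

    if ceac_df is not None:
        written["ceac"] = out_dir / "ceac.csv"
        ceac_df.to_csv(written["ceac"], index=False)
        written["ceac_plot"] = out_dir / "ceac.png"
        _plot_ceac(ceac_df, written["ceac_plot"])

    written["summary"] = out_dir / "summary.json"
    with open(written["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if manifest is not None:
        written["manifest"] = out_dir / "manifest.json"
        with open(written["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return written


def _plot_tornado(tornado_df: pd.DataFrame, path: Path,
                  top_n: int = 15) -> None:
    df = tornado_df.head(top_n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    base = df["nmb_base"].iloc[0]
    lo = np.minimum(df["nmb_at_low"], df["nmb_at_high"])
    hi = np.maximum(df["nmb_at_low"], df["nmb_at_high"])
    ax.barh(df["parameter"], hi - lo, left=lo, color="#4878d0")
    ax.axvline(base, color="k", lw=1, ls="--")
    ax.set_xlabel("Net monetary benefit of self-management (USD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_ce_plane(psa_result: PSAResult, path: Path,
                   reference: str = "UC",
                   perspective: str = "societal") -> None:
    q = psa_result.pivot("qalys")
    c = psa_result.pivot(psa_result.cost_column(perspective))
    fig, ax = plt.subplots(figsize=(7, 6))
    for strat in q.columns:
        if strat == reference:
            continue
        ax.scatter(q[strat] - q[reference], c[strat] - c[reference],
                   s=6, alpha=0.4, label=f"{strat} vs {reference}")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_ceac(ceac_df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for col in ceac_df.columns:
        if col == "wtp":
            continue
        ax.plot(ceac_df["wtp"], ceac_df[col], label=col)
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("Probability most cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
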