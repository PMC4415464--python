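"""Tabular and config I/O for trial data, scenarios and results.

All artifacts are plain text: CSV for counts and result tables, YAML/JSON
for configuration, JSON for estimator records and run manifests.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .design import AffineScoreRule, TrialData, TwoStageDesign
from .intervals import IntervalResult
from .simulate import ScenarioSpec

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_scenario",
    "estimate_record",
    "intervals_to_frame",
    "write_manifest",
]

PathLike = Union[str, Path]

_STAGE2_LABEL = "stage2"


def read_trial_csv(path: PathLike) -> TrialData:
    """Read observed trial counts from CSV.

    Layout: one row per classifier with columns ``index, n1, x, c, lam``
    (``lam`` optional, defaulting to ``n1`` — the sensitivity ranking), plus
    a final row with ``index == "stage2"`` whose ``n1`` and ``x`` columns
    hold the stage-2 size ``n2`` and count ``y``.  For a trial that stopped
    at stage 1 the stage-2 row carries an empty ``x``.
    """
    df = pd.read_csv(path, comment="#", dtype={"index": str})
    required = {"index", "n1", "x", "c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    s2 = df[df["index"].str.lower() == _STAGE2_LABEL]
    if len(s2) != 1:
        raise ValueError(f"{path}: expected exactly one '{_STAGE2_LABEL}' row")
    rows = df[df["index"].str.lower() != _STAGE2_LABEL]
    if rows.empty:
        raise ValueError(f"{path}: no classifier rows")
    n1 = tuple(int(v) for v in rows["n1"])
    x = tuple(int(v) for v in rows["x"])
    c = tuple(float(v) for v in rows["c"])
    if "lam" in rows.columns and rows["lam"].notna().all():
        lam = tuple(int(v) for v in rows["lam"])
    else:
        lam = n1
    n2 = int(s2["n1"].iloc[0])
    y_raw = s2["x"].iloc[0]
    y = None if pd.isna(y_raw) else int(y_raw)
    design = TwoStageDesign(
        n1=n1, c=c, n2=n2, ranking=AffineScoreRule(scale=lam, offset=(0,) * len(lam))
    )
    return TrialData(design=design, x=x, y=y)


def write_trial_csv(trial: TrialData, path: PathLike) -> None:
    rows = [
        {
            "index": str(i + 1),
            "n1": trial.design.n1[i],
            "x": trial.x[i],
            "c": trial.design.c[i],
        }
        for i in range(trial.design.K)
    ]
    rows.append(
        {"index": _STAGE2_LABEL, "n1": trial.design.n2, "x": trial.y, "c": None}
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenario(path: PathLike) -> ScenarioSpec:
    """Read a simulation scenario from YAML or JSON.

    Keys: ``S`` (true sensitivities), ``n1``, ``c``, ``n2``, and optionally
    ``nsim``, ``seed``, ``B``.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    for key in ("S", "n1", "c", "n2"):
        if key not in cfg:
            raise ValueError(f"{path}: missing scenario key {key!r}")
    design = TwoStageDesign(
        n1=tuple(cfg["n1"]), c=tuple(cfg["c"]), n2=int(cfg["n2"])
    )
    return ScenarioSpec(
        S=tuple(cfg["S"]),
        design=design,
        nsim=int(cfg.get("nsim", 100_000)),
        seed=cfg.get("seed"),
        B=int(cfg.get("B", 10_000)),
    )


def estimate_record(trial: TrialData, method: str, estimate: float) -> dict:
    """JSON-serialisable record of one point estimate with its conditioning."""
    from .estimators import restricted_support, sufficient_statistic

    stat = sufficient_statistic(trial)
    supp = restricted_support(stat, trial.design)
    return {
        "method": method,
        "estimate": estimate,
        "conditioning": {
            "M": stat.M,
            "L": stat.L,
            "z1": stat.z1,
            "support": [supp.lo, supp.hi],
            "kind": supp.kind,
        },
    }


def intervals_to_frame(results: Sequence[IntervalResult]) -> pd.DataFrame:
    """One row per interval: bounds, width and construction metadata."""
    rows = []
    for r in results:
        d = asdict(r)
        d["width"] = r.width
        rows.append(d)
    return pd.DataFrame(rows)


def write_manifest(
    out_dir: PathLike, config: dict, seed: Optional[int], t0: float
) -> Path:
    """Write a reproducibility manifest next to a command's artifacts."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "twostagedx",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "wall_clock_s": round(time.time() - t0, 3),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
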