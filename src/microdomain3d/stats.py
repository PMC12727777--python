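"""Per-sphere metric aggregation: mean, median, SD, coefficient of variation.

CV = standard deviation / sample mean (dimensionless). The SD is the sample
standard deviation (n-1 denominator) by default; a population switch exists
for sensitivity checks. MAM areas are summarised over MAM-positive spheres
only — microdomains without mitochondria have no MAM by definition and are
omitted rather than counted as zero, which would distort the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import MicrodomainMetrics

ALL = "all"
MAM_POSITIVE_ONLY = "mam_positive_only"


@dataclass
class SummaryStats:
    metric_name: str
    inclusion_rule: str
    n: int
    mean: float
    median: float
    sd: float | None        # None when n == 1
    cv: float | None        # sd/mean; None when sd is None or mean == 0


def summarize(
    values: Sequence[float],
    rule: str = ALL,
    flags: Sequence[bool] | None = None,
    metric_name: str = "",
    population_sd: bool = False,
) -> SummaryStats:
    """Summary statistics of a metric over spheres, honouring the inclusion rule.

    With ``rule=MAM_POSITIVE_ONLY`` the ``flags`` sequence marks MAM-positive
    spheres and only those values are aggregated.
    """
    vals = np.asarray(values, dtype=float)
    if rule == MAM_POSITIVE_ONLY:
        if flags is None:
            raise ValueError("rule 'mam_positive_only' requires per-value flags")
        vals = vals[np.asarray(flags, dtype=bool)]
    elif rule != ALL:
        raise ValueError(f"unknown inclusion rule {rule!r}")
    if vals.size == 0:
        raise ValueError(f"no values left to summarise under rule {rule!r}")
    mean = float(vals.mean())
    median = float(np.median(vals))
    if vals.size == 1:
        sd = cv = None
    else:
        sd = float(vals.std(ddof=0 if population_sd else 1))
        cv = sd / mean if mean != 0.0 else None
    return SummaryStats(metric_name, rule, int(vals.size), mean, median, sd, cv)


def _fmt(x: float | None) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else repr(float(x))


def report(
    per_sphere: "Iterable[MicrodomainMetrics]",
    out_dir: str | Path,
    provenance: dict | None = None,
) -> tuple[Path, Path]:
    """Write the per-sphere CSV and the summary CSV; returns both paths.

    Summary rows: ER volume and ASD over all spheres, MAM area over
    MAM-positive spheres only. Provenance (radius, seed, thresholds,
    software version) is appended as constant columns so a summary file is
    self-describing. Output is deterministic: identical inputs give
    byte-identical files.
    """
    from . import __version__

    records = list(per_sphere)
    if not records:
        raise ValueError("report needs at least one per-sphere record")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_rows = []
    for m in records:
        per_rows.append(
            {
                "sphere_id": m.sphere_id,
                "asd_nm": m.asd_nm,
                "n_pm_vertices": m.n_pm_vertices,
                "er_volume_nm3": m.er_volume_nm3,
                "has_mito": m.has_mito,
                "mam_area_total_nm2": "" if m.mam_area_total_nm2 is None else m.mam_area_total_nm2,
                "n_proximity_events": m.n_proximity_events,
            }
        )
    per_path = out_dir / "per_sphere.csv"
    pd.DataFrame(per_rows).to_csv(per_path, index=False)

    flags = [m.has_mito for m in records]
    rows = []
    specs = [
        ("er_volume_nm3", [m.er_volume_nm3 for m in records], ALL, None),
        ("asd_nm", [m.asd_nm for m in records], ALL, None),
        (
            "mam_area_total_nm2",
            [m.mam_area_total_nm2 if m.mam_area_total_nm2 is not None else np.nan for m in records],
            MAM_POSITIVE_ONLY,
            flags,
        ),
    ]
    for name, vals, rule, fl in specs:
        try:
            s = summarize(vals, rule=rule, flags=fl, metric_name=name)
        except ValueError:
            continue  # e.g. no MAM-positive sphere at all
        rows.append(
            {
                "metric": s.metric_name,
                "inclusion_rule": s.inclusion_rule,
                "n": s.n,
                "mean": _fmt(s.mean),
                "median": _fmt(s.median),
                "sd": _fmt(s.sd),
                "cv": _fmt(s.cv),
            }
        )
    summary = pd.DataFrame(rows)
    prov = {"software_version": __version__}
    prov.update(provenance or {})
    for key, val in sorted(prov.items()):
        summary[key] = str(val)
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False)
    return per_path, summary_path
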