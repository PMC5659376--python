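"""Conductance-space firing-parameter maps.

Scans the (Kv7.4, Kv1-type) conductance plane — by default 0–2000 nS in
100-nS steps by 0–1000 nS in 20-nS steps, 21 x 51 = 1071 combinations per
Kvb2 mode — and computes, per grid point, the threshold current, first-AP
latency at 1T, AP counts at 1.5T and 2T, the ISI adaptation ratio at 2T,
and the phenotype label.  Cells that never fire below the search ceiling
are flagged non-firing with the ceiling recorded as a sentinel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcell import (MCellModel, RateCalibration, DEFAULT_CALIBRATION,
                    STEP_SEARCH_CEILING_PA, find_threshold, run_intensity_series)
from .metrics import classify_phenotype, compute_metrics, detect_spikes

__all__ = ["SweepGrid", "SweepResult", "run_sweep", "export_maps", "read_maps"]

MAP_COLUMNS = ("threshold_pA", "latency_1T_ms", "nAP_1p5T", "nAP_2T", "isi_ratio_2T")


@dataclass(frozen=True)
class SweepGrid:
    """Grid over (Kv7.4, Kv1-type) maximal conductances in nS."""

    kv74_axis_nS: tuple = tuple(range(0, 2001, 100))
    kv1_axis_nS: tuple = tuple(range(0, 1001, 20))
    kvb2_mode: bool = False

    @property
    def n_points(self) -> int:
        return len(self.kv74_axis_nS) * len(self.kv1_axis_nS)

    def points(self):
        for g74 in self.kv74_axis_nS:
            for g1 in self.kv1_axis_nS:
                yield float(g74), float(g1)


@dataclass
class SweepResult:
    grid: SweepGrid
    table: pd.DataFrame  # one row per grid point, grid order

    def map2d(self, column: str) -> pd.DataFrame:
        """Pivot one metric into a (kv74 x kv1) matrix."""
        return self.table.pivot(index="gKv74_nS", columns="gKv1_nS", values=column)


def _evaluate_point(g74, g1, grid, calibration, dt_ms, ceiling_pA):
    model = MCellModel(g_kv74_nS=g74, g_kv1_nS=g1, kvb2=grid.kvb2_mode,
                       calibration=calibration)
    row = {
        "gKv74_nS": g74,
        "gKv1_nS": g1,
        "kvb2": grid.kvb2_mode,
        "error": "",
    }
    try:
        T = find_threshold(model, dt_ms=dt_ms, ceiling_pA=ceiling_pA)
    except RuntimeError:
        row.update(threshold_pA=float(ceiling_pA), latency_1T_ms=np.nan,
                   nAP_1p5T=0, nAP_2T=0, isi_ratio_2T=np.nan,
                   phenotype="non_firing")
        return row
    try:
        traces = run_intensity_series(model, T, dt_ms=dt_ms)
        trains = {k: detect_spikes(v) for k, v in traces.items()}
        metrics = compute_metrics(trains, T)
        row.update(
            threshold_pA=float(T),
            latency_1T_ms=metrics.latency_1T_ms,
            nAP_1p5T=metrics.n_spikes[1.5],
            nAP_2T=metrics.n_spikes[2.0],
            isi_ratio_2T=(np.nan if metrics.adaptation_ratio is None
                          else metrics.adaptation_ratio),
            phenotype=classify_phenotype(metrics),
        )
    except RuntimeError as exc:  # recorded, never silently dropped
        row.update(threshold_pA=float(T), latency_1T_ms=np.nan,
                   nAP_1p5T=-1, nAP_2T=-1, isi_ratio_2T=np.nan,
                   phenotype="error", error=str(exc))
    return row


def run_sweep(
    grid: SweepGrid = SweepGrid(),
    calibration: RateCalibration = DEFAULT_CALIBRATION,
    dt_ms: float = 0.025,
    ceiling_pA: int = STEP_SEARCH_CEILING_PA,
    progress: bool = False,
) -> SweepResult:
    """Evaluate every grid point; deterministic and order-independent."""
    rows = []
    points = list(grid.points())
    for i, (g74, g1) in enumerate(points):
        rows.append(_evaluate_point(g74, g1, grid, calibration, dt_ms, ceiling_pA))
        if progress and (i + 1) % 100 == 0:
            print(f"  sweep {i + 1}/{len(points)}", flush=True)
    table = pd.DataFrame(rows)
    return SweepResult(grid=grid, table=table)


def export_maps(result: SweepResult, outdir, write_matrices: bool = True) -> Path:
    """Write the tidy per-point table and optional per-map matrix files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = "kvb2" if result.grid.kvb2_mode else "kv11"
    tidy = outdir / f"sweep_{mode}.tsv"
    result.table.to_csv(tidy, sep="\t", index=False, float_format="%.9g")
    if write_matrices:
        for col in MAP_COLUMNS:
            result.map2d(col).to_csv(outdir / f"map_{mode}_{col}.tsv",
                                     sep="\t", float_format="%.9g")
    return tidy


def read_maps(tidy_path) -> pd.DataFrame:
    """Re-import a tidy sweep table written by :func:`export_maps`."""
    return pd.read_csv(tidy_path, sep="\t", keep_default_na=False,
                       na_values=[""],
                       dtype={"error": str})
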