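"""Programmed-stimulation measures from intracardiac electrophysiology.

Covers sinus-node recovery time (SNRT, and its rate-corrected form cSNRT),
sinoatrial conduction time (SACT) from premature atrial stimulation,
atrioventricular conduction/latency curves with the functional refractory
period (FRP), and effective refractory periods (ERP) from S1S2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SanephysError

DEFAULT_EPSILON_MS = 5.0  # tolerance for the fully-compensatory identity


def compute_snrt(
    last_stim_time_s: float,
    first_spontaneous_atrial_time_s: float,
    mean_scl_ms: float,
) -> tuple[float, float]:
    """SNRT and cSNRT in ms.

    SNRT is the interval from the last pacing spike to the first spontaneous
    sinus-triggered atrial activation; cSNRT subtracts the averaged sinus
    cycle length.
    """
    if mean_scl_ms <= 0:
        raise ValueError("mean_scl_ms must be positive")
    snrt = (first_spontaneous_atrial_time_s - last_stim_time_s) * 1000.0
    if snrt <= 0:
        raise ValueError("first spontaneous beat must follow the last stimulus")
    return snrt, snrt - mean_scl_ms


@dataclass
class SactResult:
    sact: float          # ms
    reset_onset: float   # ms, longest A1A2 in the reset zone
    zones: pd.DataFrame  # input rows + zone label
    plateau_sact: float  # ms, mean over all reset-zone rows
    plateau_detected: bool

    def summary(self) -> str:
        return (
            f"SACT {self.sact:.1f} ms (first deviating row; plateau mean "
            f"{self.plateau_sact:.1f} ms), reset onset at A1A2 "
            f"{self.reset_onset:.1f} ms"
        )


def compute_sact(
    table: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON_MS,
    use_plateau_mean: bool = False,
) -> SactResult:
    """Sinoatrial conduction time from a premature-stimulation table.

    Rows satisfying the fully-compensatory identity |A1A2 + A2A3 - 2*A1A1|
    <= epsilon are labelled ``compensatory``. Scanning A1A2 in descending
    order, the first row that deviates beyond epsilon (with A2A3 > A1A1)
    marks the reset zone; SACT = (A2A3 - A1A1)/2 there. With
    ``use_plateau_mean`` the estimate averages over all reset-zone rows.
    """
    cols = {c.lower(): c for c in table.columns}
    a1a1 = table[cols["a1a1_ms"]].to_numpy(dtype=float)
    a1a2 = table[cols["a1a2_ms"]].to_numpy(dtype=float)
    a2a3 = table[cols["a2a3_ms"]].to_numpy(dtype=float)

    dev = a1a2 + a2a3 - 2.0 * a1a1
    compensatory = np.abs(dev) <= epsilon
    reset = (~compensatory) & (a2a3 > a1a1)
    labels = np.where(compensatory, "compensatory",
                      np.where(reset, "reset", "other"))
    zones = table.copy()
    zones["zone"] = labels

    if not reset.any():
        raise SanephysError("no reset zone observed: all rows compensatory")
    if not compensatory.any():
        raise SanephysError("no compensatory zone observed")

    order = np.argsort(a1a2)[::-1]
    first = next(i for i in order if reset[i])
    sact_first = (a2a3[first] - a1a1[first]) / 2.0
    reset_sacts = (a2a3[reset] - a1a1[reset]) / 2.0
    plateau_mean = float(np.mean(reset_sacts))
    plateau = reset.sum() >= 3 and float(np.ptp(a2a3[reset])) <= 2.0 * epsilon
    return SactResult(
        sact=plateau_mean if use_plateau_mean else float(sact_first),
        reset_onset=float(a1a2[first]),
        zones=zones,
        plateau_sact=plateau_mean,
        plateau_detected=bool(plateau),
    )


@dataclass
class AvConductionResult:
    frp: float                 # ms, shortest V1V2
    curve: pd.DataFrame        # (a1a2_ms, v1v2_ms) sorted by A1A2
    latency: pd.DataFrame      # (a1a2_ms, a2v2_ms)
    hv_mismatch: pd.DataFrame  # rows where V1V2 and H1H2 disagree


def av_conduction_curves(
    table: pd.DataFrame, hv_tolerance: float = 2.0
) -> AvConductionResult:
    """AV conduction curve, latency curve, and functional refractory period.

    FRP is the shortest V1V2 output interval. Rows where H1H2 deviates from
    V1V2 beyond ``hv_tolerance`` are flagged (conduction delay not confined
    to the AV node).
    """
    if table.empty:
        raise SanephysError("empty premature-stimulation table")
    cols = {c.lower(): c for c in table.columns}
    a1a2 = table[cols["a1a2_ms"]].to_numpy(dtype=float)
    v1v2 = table[cols["v1v2_ms"]].to_numpy(dtype=float)
    order = np.argsort(a1a2)
    curve = pd.DataFrame({"a1a2_ms": a1a2[order], "v1v2_ms": v1v2[order]})
    latency = pd.DataFrame()
    if "a2v2_ms" in cols:
        a2v2 = table[cols["a2v2_ms"]].to_numpy(dtype=float)
        latency = pd.DataFrame({"a1a2_ms": a1a2[order], "a2v2_ms": a2v2[order]})
    mismatch = pd.DataFrame()
    if "h1h2_ms" in cols:
        h1h2 = table[cols["h1h2_ms"]].to_numpy(dtype=float)
        bad = np.abs(h1h2 - v1v2) > hv_tolerance
        mismatch = table.loc[bad]
    return AvConductionResult(
        frp=float(np.min(v1v2)), curve=curve, latency=latency,
        hv_mismatch=mismatch,
    )


def find_erp(table: pd.DataFrame) -> float:
    """Effective refractory period: the longest non-conducted S1S2 (ms)."""
    cols = {c.lower(): c for c in table.columns}
    s1s2 = table[cols["s1s2_ms"]].to_numpy(dtype=float)
    conducted = table[cols["conducted"]].to_numpy(dtype=bool)
    if conducted.all():
        raise SanephysError("ERP not reached: every extrastimulus conducted")
    return float(np.max(s1s2[~conducted]))


def automaticity_ratio(table: pd.DataFrame) -> float:
    """Diagnostic A3A4/A1A1 ratio (post-return vs spontaneous cycle)."""
    cols = {c.lower(): c for c in table.columns}
    a3a4 = table[cols["a3a4_ms"]].to_numpy(dtype=float)
    a1a1 = table[cols["a1a1_ms"]].to_numpy(dtype=float)
    return float(np.mean(a3a4 / a1a1))
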