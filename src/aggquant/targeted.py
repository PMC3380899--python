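"""Targeted MS/MS quantification with AGC inject-time correction.

Fragment intensities from targeted scans are summed over a required
fragment list (all required ions must be present), rescaled by
``150 ms / (ion inject time)`` to cancel automatic gain control, normalized
to constitutively insoluble reference peptides, and summarized as
log2(experimental/control) with a 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Maximum ion inject time of the trap (ms); the AGC correction reference.
MAX_INJECT_MS = 150.0

#: Ion-trap MS/MS fragment matching tolerance (m/z).
FRAGMENT_TOLERANCE = 0.5


@dataclass
class TargetedScan:
    """One targeted MS/MS scan: fragment peaks plus the ion inject time."""

    peptide_id: str
    sample: str
    replicate: int
    inject_time_ms: float
    peaks: list[tuple[float, float]]
    precursor_mz: float = 0.0
    scan_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inject_time_ms <= MAX_INJECT_MS):
            raise ValueError(
                f"inject time must be in (0, {MAX_INJECT_MS}] ms, got "
                f"{self.inject_time_ms}"
            )


def sum_required_fragments(
    scan: TargetedScan,
    required: list[float],
    tolerance: float = FRAGMENT_TOLERANCE,
) -> float | None:
    """Sum intensities of the required fragments, or ``None`` if any is absent.

    Every required fragment must have a peak within ``tolerance`` m/z for a
    positive identification; each fragment takes its closest matching peak.
    """
    if len(required) < 2:
        raise ValueError("at least 2 required fragments are needed")
    if not scan.peaks:
        return None
    mzs = np.array([p[0] for p in scan.peaks])
    total = 0.0
    for frag in required:
        deltas = np.abs(mzs - frag)
        idx = int(np.argmin(deltas))
        if deltas[idx] > tolerance:
            return None
        total += scan.peaks[idx][1]
    return total


def agc_correct(summed_intensity: float, inject_time_ms: float) -> float:
    """Rescale by ``150 / inject_time`` so intensities are comparable across
    scans with different trap fill times."""
    if inject_time_ms <= 0:
        raise ValueError(f"inject time must be positive, got {inject_time_ms}")
    return summed_intensity * MAX_INJECT_MS / inject_time_ms


def xic_quantify(
    trace: list[tuple[float, float]], window: tuple[float, float]
) -> float | None:
    """Apex (maximum) precursor intensity within the elution window; the
    precursor signal is not subject to AGC so no correction applies."""
    if not trace:
        raise ValueError("empty precursor trace")
    lo, hi = window
    in_window = [inten for t, inten in trace if lo <= t <= hi]
    return max(in_window) if in_window else None


@dataclass
class TargetedResult:
    """Reference-normalized log2 ratio with confidence interval."""

    peptide_id: str
    values: list[float]
    mean_log2: float
    ci95: float
    percent_change: float
    n: int
    excluded: list[str] = field(default_factory=list)


def normalize_and_summarize(
    target: dict[tuple[str, int], float],
    references: dict[str, dict[tuple[str, int], float]],
    experimental: str,
    control: str,
    peptide_id: str = "",
    ci_mode: str = "t",
) -> TargetedResult:
    """Summarize one peptide's experimental/control change.

    ``target`` and each reference map ``(sample, replicate)`` to intensity.
    For every reference and replicate present in both conditions, the
    normalized ratio is ``(target/ref)_exp / (target/ref)_ctl``; the mean
    log2 is taken over all k = references x replicates values, with
    ``ci95 = t_{0.975, k-1} * SD / sqrt(k)`` (``ci_mode="normal"`` uses
    1.96 instead of the t quantile).  Samples missing a reference are
    excluded and logged.  Percent change is ``100 * (2**mean - 1)``.
    """
    excluded: list[str] = []
    values: list[float] = []
    replicates = sorted({rep for (_s, rep) in target})
    for ref_name, ref in references.items():
        for rep in replicates:
            keys = [(experimental, rep), (control, rep)]
            if any(k not in target for k in keys):
                excluded.append(f"target missing in {keys} (replicate {rep})")
                continue
            if any(k not in ref or ref[k] <= 0 for k in keys):
                excluded.append(
                    f"reference {ref_name} missing in replicate {rep}; sample excluded"
                )
                continue
            norm_exp = target[(experimental, rep)] / ref[(experimental, rep)]
            norm_ctl = target[(control, rep)] / ref[(control, rep)]
            values.append(float(np.log2(norm_exp / norm_ctl)))
    if not values:
        raise ValueError(f"no normalized values for {peptide_id or 'target'}")
    arr = np.asarray(values)
    mean = float(arr.mean())
    k = arr.size
    if k > 1:
        sd = float(arr.std(ddof=1))
        quantile = float(stats.t.ppf(0.975, k - 1)) if ci_mode == "t" else 1.96
        ci95 = quantile * sd / np.sqrt(k)
    else:
        ci95 = float("nan")
    return TargetedResult(
        peptide_id=peptide_id,
        values=values,
        mean_log2=mean,
        ci95=float(ci95),
        percent_change=percent_change(mean),
        n=k,
        excluded=excluded,
    )


def percent_change(mean_log2: float) -> float:
    """``100 * (2**mean - 1)``: a log2 ratio of 0.70 is a 62% increase."""
    return 100.0 * (2.0 ** float(mean_log2) - 1.0)


def quantify_scan_table(
    scans: pd.DataFrame,
    required: dict[str, list[float]],
    tolerance: float = FRAGMENT_TOLERANCE,
) -> dict[str, dict[tuple[str, int], float]]:
    """AGC-corrected apex intensity per (peptide, sample, replicate).

    ``scans`` columns: peptide_id, sample, replicate, inject_time_ms,
    fragments (either a peak list or a ``mz:intensity;...`` string).  Scans
    failing the all-required-fragments rule are dropped; of the remaining
    scans for one peptide/sample the apex (maximum corrected intensity) is
    kept.
    """
    out: dict[str, dict[tuple[str, int], float]] = {}
    for row in scans.itertuples():
        peaks = row.fragments
        if isinstance(peaks, str):
            peaks = [
                (float(pair.split(":")[0]), float(pair.split(":")[1]))
                for pair in peaks.split(";")
                if pair
            ]
        scan = TargetedScan(
            peptide_id=row.peptide_id,
            sample=row.sample,
            replicate=int(row.replicate),
            inject_time_ms=float(row.inject_time_ms),
            peaks=peaks,
        )
        summed = sum_required_fragments(scan, required[scan.peptide_id], tolerance)
        if summed is None:
            continue
        corrected = agc_correct(summed, scan.inject_time_ms)
        key = (scan.sample, scan.replicate)
        table = out.setdefault(scan.peptide_id, {})
        table[key] = max(table.get(key, 0.0), corrected)
    return out


def quantify_trace_table(
    traces: pd.DataFrame, window: tuple[float, float] | None = None
) -> dict[str, dict[tuple[str, int], float]]:
    """Apex XIC intensity per (peptide, sample, replicate) from precursor
    traces with columns peptide_id, sample, replicate, time, intensity."""
    out: dict[str, dict[tuple[str, int], float]] = {}
    for (pid, sample, rep), grp in traces.groupby(["peptide_id", "sample", "replicate"]):
        trace = list(zip(grp["time"], grp["intensity"]))
        win = window if window is not None else (min(grp["time"]), max(grp["time"]))
        apex = xic_quantify(trace, win)
        if apex is not None:
            out.setdefault(pid, {})[(sample, int(rep))] = apex
    return out
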