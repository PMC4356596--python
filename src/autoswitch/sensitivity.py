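"""One-at-a-time parameter robustness analysis.

For each rate constant the model is re-parameterized over 17 log-spaced
multipliers 10^(n/4), n = -8..8 (100-fold below to 100-fold above nominal),
and the response of the system to each of the two stress inputs is scanned:
AMPK* from 0 to 10^6 copies/cell with rapamycin* absent, and rapamycin* from
0 to 10^5 copies/cell with AMPK* at 3x10^4 copies/cell.  A scan is
*canonical* when the regime sequence along the input is exactly
translation -> oscillatory -> autophagy, each non-empty and uninterrupted —
the characteristic three-regime response pattern of the nominal model.  The
robustness range of a parameter is the largest contiguous run of multipliers
containing the nominal value for which both scans stay canonical.

Scans are realized as slow up-drift sweeps of the input (the protocol used
to generate the response-pattern examples), with windowed regime labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import SENSITIVITY_PARAMETERS
from .network import ReactionNetwork
from .bifurcation import Sweep, SweepConfig, label_sweep_windows, slow_drift_sweep

#: the two input scans: (input name, low, high, fixed other input)
SCANS: dict[str, dict] = {
    "ampk": {"param": "ampk_star", "lo": 0.0, "hi": 1e6,
             "fixed": {"rapamycin_star": 0.0}},
    "rapa": {"param": "rapamycin_star", "lo": 0.0, "hi": 1e5,
             "fixed": {"ampk_star": 3e4}},
}

#: 17 multiplier exponents n (multiplier = 10^(n/4))
FULL_EXPONENTS: tuple[int, ...] = tuple(range(-8, 9))
#: reduced exponent set for quick runs
QUICK_EXPONENTS: tuple[int, ...] = (-8, -3, 0, 3, 8)

CANONICAL_SEQUENCE: tuple[str, ...] = ("translation", "oscillatory", "autophagy")


class SensitivityError(RuntimeError):
    pass


@dataclass
class ResponsePattern:
    """Regime sequence along one input scan."""

    input_name: str
    centers: np.ndarray
    window_labels: list[str]
    sequence: tuple[str, ...]
    canonical: bool
    classifiable: bool = True


def collapse_labels(labels: Sequence[str]) -> tuple[str, ...]:
    """Collapse window labels to a regime sequence: transition windows (branch
    jumps, cycles slower than a window) are dropped, consecutive duplicates
    merged."""
    seq: list[str] = []
    for lab in labels:
        if lab == "transition":
            continue
        if not seq or seq[-1] != lab:
            seq.append(lab)
    return tuple(seq)


def _has_oscillation(network: ReactionNetwork, params: dict[str, float],
                     input_name: str, lo: float, hi: float,
                     amp_thresh: float, depth: int,
                     sweep_kwargs: Optional[dict]) -> bool:
    """Does the response oscillate somewhere in the input subrange?

    Sweeps the subrange with drift scaled to its width (so narrow ambiguous
    regions are traversed proportionally more slowly) and looks for at least
    three prominent peaks; recurses once more on any still-ambiguous run.
    """
    from scipy.signal import find_peaks

    cfg = SweepConfig(input_name, lo, hi, "up", **(sweep_kwargs or {}))
    sweep = slow_drift_sweep(network, params, cfg)
    peaks, _ = find_peaks(sweep.frac_ambra, prominence=amp_thresh)
    if len(peaks) >= 3:
        return True
    if depth <= 0:
        return False
    _, labels = label_sweep_windows(sweep, 8, amp_thresh)
    if "oscillatory" in labels:
        return True
    edges = np.linspace(lo, hi, 9)
    for run_lo, run_hi in _ambiguous_runs(labels, edges):
        if _has_oscillation(network, params, input_name, run_lo, run_hi,
                            amp_thresh, depth - 1, sweep_kwargs):
            return True
    return False


def _ambiguous_runs(labels: Sequence[str], edges: np.ndarray
                    ) -> list[tuple[float, float]]:
    """Input spans of maximal contiguous runs of transition windows."""
    runs = []
    start = None
    for k, lab in enumerate(labels):
        if lab == "transition" and start is None:
            start = k
        elif lab != "transition" and start is not None:
            runs.append((float(edges[start]), float(edges[k])))
            start = None
    if start is not None:
        runs.append((float(edges[start]), float(edges[-1])))
    return runs


def classify_response(network: ReactionNetwork, params: dict[str, float],
                      input_name: str, lo: float, hi: float,
                      n_windows: int = 40,
                      amp_thresh: float = 0.01,
                      refine_depth: int = 1,
                      sweep_kwargs: Optional[dict] = None) -> ResponsePattern:
    """Scan one input by a slow up-drift sweep and classify the response.

    Window labeling under-resolves oscillations whose period approaches the
    window span (near a SNIC onset the period diverges), so maximal runs of
    transition windows are re-examined: the subrange is re-swept with drift
    scaled to its width and relabeled ``oscillatory`` if sustained peaks
    emerge.  Canonical means the collapsed regime sequence is exactly
    translation -> oscillatory -> autophagy.
    """
    cfg = SweepConfig(input_name, lo, hi, "up", **(sweep_kwargs or {}))
    sweep = slow_drift_sweep(network, params, cfg)
    centers, labels = label_sweep_windows(sweep, n_windows, amp_thresh)
    if "oscillatory" not in labels and refine_depth > 0:
        edges = np.linspace(lo, hi, n_windows + 1)
        for k_run, (run_lo, run_hi) in enumerate(_ambiguous_runs(labels, edges)):
            if _has_oscillation(network, params, input_name, run_lo, run_hi,
                                amp_thresh, refine_depth, sweep_kwargs):
                labels = [
                    "oscillatory"
                    if lab == "transition" and run_lo <= c <= run_hi else lab
                    for c, lab in zip(centers, labels)
                ]
                break
    seq = collapse_labels(labels)
    classifiable = "undetermined" not in labels
    return ResponsePattern(
        input_name=input_name,
        centers=centers,
        window_labels=labels,
        sequence=seq,
        canonical=classifiable and seq == CANONICAL_SEQUENCE,
        classifiable=classifiable,
    )


def _scan_canonical(network: ReactionNetwork, params: dict[str, float],
                    scan: dict, n_windows: int,
                    sweep_kwargs: Optional[dict]) -> bool:
    p = dict(params)
    p.update(scan["fixed"])
    pattern = classify_response(network, p, scan["param"], scan["lo"],
                                scan["hi"], n_windows=n_windows,
                                sweep_kwargs=sweep_kwargs)
    return pattern.canonical


CacheKey = tuple[str, int, str]


def is_canonical(network: ReactionNetwork, params: dict[str, float],
                 parameter: str, exponent: int,
                 n_windows: int = 40,
                 cache: Optional[dict[CacheKey, bool]] = None,
                 scans: Sequence[str] = ("ampk", "rapa"),
                 sweep_kwargs: Optional[dict] = None) -> bool:
    """Are the selected input scans canonical with ``parameter`` scaled by
    10^(n/4)?  By default both scans must be canonical."""
    mult = 10.0 ** (exponent / 4.0)
    p = dict(params)
    p[parameter] = params[parameter] * mult
    for scan_name in scans:
        scan = SCANS[scan_name]
        key = (parameter, exponent, scan_name)
        if cache is not None and key in cache:
            ok = cache[key]
        else:
            ok = _scan_canonical(network, p, scan, n_windows, sweep_kwargs)
            if cache is not None:
                cache[key] = ok
        if not ok:
            return False
    return True


@dataclass
class RobustnessRange:
    """Fig-8-style robustness bar for one parameter."""

    parameter: str
    exponents: tuple[int, ...]        # grid actually used
    n_lo: Optional[int]               # lowest passing exponent (None: nominal fails)
    n_hi: Optional[int]
    diagnostic: str = ""

    @property
    def empty(self) -> bool:
        return self.n_lo is None

    @property
    def mult_lo(self) -> Optional[float]:
        return None if self.n_lo is None else 10.0 ** (self.n_lo / 4.0)

    @property
    def mult_hi(self) -> Optional[float]:
        return None if self.n_hi is None else 10.0 ** (self.n_hi / 4.0)

    @property
    def fully_robust(self) -> bool:
        return (not self.empty and self.n_lo == min(self.exponents)
                and self.n_hi == max(self.exponents))

    @property
    def width(self) -> int:
        if self.empty:
            return 0
        exps = sorted(self.exponents)
        return exps.index(self.n_hi) - exps.index(self.n_lo) + 1


def robustness_range(network: ReactionNetwork, params: dict[str, float],
                     parameter: str,
                     exponents: Sequence[int] = FULL_EXPONENTS,
                     n_windows: int = 40,
                     cache: Optional[dict[CacheKey, bool]] = None,
                     scans: Sequence[str] = ("ampk", "rapa"),
                     sweep_kwargs: Optional[dict] = None,
                     progress: Optional[Callable[[str], None]] = None
                     ) -> RobustnessRange:
    """Largest contiguous multiplier run containing nominal (n = 0) on which
    both input scans remain canonical.

    Scans outward from n = 0 and stops at the first failure on each side, so
    the result is contiguous and contains the nominal multiplier by
    construction.
    """
    if parameter == "p9" or parameter not in params:
        raise SensitivityError(f"parameter {parameter!r} is not scanned")
    exps = sorted(exponents)
    if 0 not in exps:
        raise SensitivityError("exponent grid must contain the nominal n=0")

    def check(n: int) -> bool:
        ok = is_canonical(network, params, parameter, n, n_windows=n_windows,
                          cache=cache, scans=scans, sweep_kwargs=sweep_kwargs)
        if progress is not None:
            progress(f"{parameter} n={n:+d}: {'canonical' if ok else 'non-canonical'}")
        return ok

    if not check(0):
        return RobustnessRange(parameter, tuple(exps), None, None,
                               diagnostic="nominal response is non-canonical")
    zero = exps.index(0)
    lo = hi = 0
    for n in reversed(exps[:zero]):
        if check(n):
            lo = n
        else:
            break
    for n in exps[zero + 1:]:
        if check(n):
            hi = n
        else:
            break
    return RobustnessRange(parameter, tuple(exps), lo, hi)


@dataclass
class SensitivityResult:
    ranges: list[RobustnessRange]

    @property
    def n_fully_robust(self) -> int:
        return sum(r.fully_robust for r in self.ranges)

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ranges:
            rows.append({
                "parameter": r.parameter,
                "n_lo": r.n_lo,
                "n_hi": r.n_hi,
                "mult_lo": r.mult_lo,
                "mult_hi": r.mult_hi,
                "width": r.width,
                "fully_robust": r.fully_robust,
                "diagnostic": r.diagnostic,
            })
        return pd.DataFrame(rows)


def full_sensitivity(network: ReactionNetwork, params: dict[str, float],
                     parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
                     exponents: Sequence[int] = FULL_EXPONENTS,
                     n_windows: int = 40,
                     cache: Optional[dict[CacheKey, bool]] = None,
                     sweep_kwargs: Optional[dict] = None,
                     progress: Optional[Callable[[str], None]] = None
                     ) -> SensitivityResult:
    """Robustness bars for every scanned rate constant (p9 excluded).

    The full 22-parameter x 17-multiplier x 2-scan protocol is hours-scale on
    one CPU; pass ``exponents=QUICK_EXPONENTS`` and/or a parameter subset for
    a reduced run, and a shared ``cache`` dict to make the sweep restartable.
    """
    cache = {} if cache is None else cache
    ranges = [
        robustness_range(network, params, par, exponents=exponents,
                         n_windows=n_windows, cache=cache,
                         sweep_kwargs=sweep_kwargs, progress=progress)
        for par in parameters
    ]
    return SensitivityResult(ranges)
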