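"""Voxel-wise mono-exponential T2 / T1rho map reconstruction.

Maps are reconstructed from the prepared-block signals of one image
stack.  With exactly two usable blocks (preparation times 0 and tau) the
closed-form two-point estimate t = tau / ln(s1/s2) is used; with three
or more, ordinary least squares of log signal on preparation time
(log-linear fit, t = -1/slope).  Because all blocks share TR and
readout, the shared factors cancel in the ratios and the fit recovers
the water-compartment relaxation time exactly in noiseless water voxels.

Validity diagnostics, not clamping, handle voxels where the
mono-exponential model fails (notably fat under partial saturation):
a voxel is valid only if all block signals exceed a noise floor, the
signal decays (positive fitted time), and — for fits with three or more
points — the log-domain coefficient of determination exceeds a
threshold.  Fat voxels violate these because fat saturation is applied
inconsistently across blocks, grossly distorting the apparent decay;
this reproduces the "no meaningful values in fatty tissue" behavior of
fat-saturated prep-module acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import ImageStack

__all__ = [
    "ParameterMap",
    "RegionSummary",
    "fit_t2_two_point",
    "fit_monoexp_loglinear",
    "reconstruct_map",
    "summarize_region",
    "T2_MAX_MS",
    "RSQ_MIN",
]

#: Upper clamp for fitted relaxation times (keeps fluid finite under noise).
T2_MAX_MS = 2000.0
#: Minimum log-domain R^2 for >=3-point fits in diagnostics-mode masking.
RSQ_MIN = 0.95

#: Display ranges conventionally used for map rendering (ms).
DISPLAY_RANGE_MS = {"T2": (0.0, 100.0), "T1rho": (0.0, 70.0)}


@dataclass
class ParameterMap:
    """Fitted relaxation-time volume with validity mask and diagnostics."""

    values_ms: np.ndarray
    valid: np.ndarray
    s0: np.ndarray
    rsq: np.ndarray
    kind: str  # "T2" or "T1rho"

    def __post_init__(self) -> None:
        if self.kind not in ("T2", "T1rho"):
            raise ValueError("kind must be 'T2' or 'T1rho'")


@dataclass(frozen=True)
class RegionSummary:
    region: str
    mean_ms: float
    sd_ms: float
    n_voxels: int


def fit_t2_two_point(s1, s2, tau_ms: float, floor: float = 0.0):
    """Closed-form two-point mono-exponential fit.

    t = tau / ln(s1/s2), valid only where s1 > s2 > floor (a decaying
    signal above the noise floor).  Values are clamped to (0, T2_MAX_MS].
    Accepts scalars or arrays; returns (t_ms, valid).
    """
    if tau_ms <= 0:
        raise ValueError("tau_ms must be > 0")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    valid = (s1 > s2) & (s2 > floor)
    t = np.full(np.broadcast(s1, s2).shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, s1 / np.where(s2 > 0, s2, 1.0), np.e)
        t = tau_ms / np.log(ratio)
    t = np.minimum(t, T2_MAX_MS)
    t = np.where(valid, t, np.nan)
    if t.ndim == 0:
        return float(t), bool(valid)
    return t, valid


def fit_monoexp_loglinear(signals, times_ms, floor: float = 0.0):
    """OLS of log signal on preparation time; t = -1/slope.

    ``signals`` may be 1-D (one voxel) or 2-D with shape
    (n_points, n_voxels).  Returns (s0, t_ms, rsq, valid): valid requires
    all signals above ``floor`` and a negative slope.  rsq is the
    log-domain coefficient of determination (1.0 by convention when the
    fit interpolates two points exactly).
    """
    s = np.atleast_2d(np.asarray(signals, dtype=float).T).T  # (n_points, n_vox)
    t = np.asarray(times_ms, dtype=float)
    if t.ndim != 1 or t.size != s.shape[0]:
        raise ValueError("times_ms must be 1-D and match the signal count")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if np.unique(t).size != t.size:
        raise ValueError("preparation times must be distinct")
    if np.any(t < 0):
        raise ValueError("preparation times must be >= 0")

    pos = np.all(s > max(floor, 0.0), axis=0)
    logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), 0.0)
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    sxy = tc @ logs
    slope = sxy / sxx
    intercept = logs.mean(axis=0) - slope * t.mean()
    fitted = np.outer(t, slope) + intercept
    resid = logs - fitted
    sse = np.sum(resid**2, axis=0)
    sst = np.sum((logs - logs.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), 0.0)
    valid = pos & (slope < 0)
    with np.errstate(divide="ignore"):
        t_ms = np.where(slope < 0, -1.0 / np.where(slope != 0, slope, -1.0), np.nan)
    t_ms = np.minimum(t_ms, T2_MAX_MS)
    t_ms = np.where(valid, t_ms, np.nan)
    s0 = np.exp(intercept)
    rsq = np.where(valid, rsq, np.nan)
    if np.asarray(signals).ndim == 1:
        return float(s0[0]), float(t_ms[0]), float(rsq[0]), bool(valid[0])
    return s0, t_ms, rsq, valid


def _family_blocks(stack: ImageStack, kind: str):
    family = "t2prep" if kind == "T2" else "spinlock"
    idx, times = [], []
    for i, b in enumerate(stack.sequence.blocks):
        if b.prep_type == family or (b.prep_type == "none" and b.prep_time_ms == 0):
            idx.append(i)
            times.append(b.prep_time_ms)
    if not idx:
        raise ValueError(f"stack has no blocks of the {family} family")
    times = np.asarray(times, dtype=float)
    if not np.any(times == 0):
        raise ValueError("stack lacks a zero-preparation block")
    if not np.any(times > 0):
        raise ValueError(
            f"stack has no positive-{family} block; cannot fit {kind} "
            f"from sequence {stack.sequence.name!r}"
        )
    # require at least one genuinely prepared block of the right family
    if not any(
        stack.sequence.blocks[i].prep_type == family and times[j] > 0
        for j, i in enumerate(idx)
    ):
        raise ValueError(f"sequence {stack.sequence.name!r} has no {family} blocks")
    order = np.argsort(times)
    return [idx[j] for j in order], times[order]


def reconstruct_map(
    stack: ImageStack,
    kind: str,
    floor: float | None = None,
    fat_mask: np.ndarray | None = None,
    rsq_min: float = RSQ_MIN,
) -> ParameterMap:
    """Reconstruct a T2 or T1rho map from an image stack.

    Uses the closed-form two-point fit for two usable blocks and the
    log-linear fit for three or more.  ``floor`` defaults to three times
    the stack's channel noise SD.  Diagnostics-mode masking (default)
    invalidates voxels with sub-floor signals, non-decaying signals, or
    (>=3 points) log-domain R^2 below ``rsq_min``; alternatively a known
    ``fat_mask`` may be supplied and is invalidated in addition.
    """
    if kind not in ("T2", "T1rho"):
        raise ValueError("kind must be 'T2' or 'T1rho'")
    if floor is None:
        floor = 3.0 * stack.noise_sigma
    idx, times = _family_blocks(stack, kind)
    shape = stack.volumes[0].shape
    sig = np.stack([stack.volumes[i].ravel() for i in idx])  # (n_points, n_vox)

    if len(idx) == 2:
        tau = float(times[1])
        t_ms, valid = fit_t2_two_point(sig[0], sig[1], tau, floor=floor)
        s0 = sig[0].astype(float)
        rsq = np.where(valid, 1.0, np.nan)
    else:
        s0, t_ms, rsq, valid = fit_monoexp_loglinear(sig, times, floor=floor)
        bad = valid & (rsq < rsq_min)
        valid = valid & ~bad
        t_ms = np.where(valid, t_ms, np.nan)
        rsq = np.where(valid, rsq, np.nan)

    t_ms = t_ms.reshape(shape)
    valid = valid.reshape(shape)
    s0 = np.asarray(s0).reshape(shape)
    rsq = np.asarray(rsq).reshape(shape)
    if fat_mask is not None:
        if fat_mask.shape != shape:
            raise ValueError("fat_mask shape mismatch")
        valid = valid & ~fat_mask
        t_ms = np.where(valid, t_ms, np.nan)
    return ParameterMap(values_ms=t_ms, valid=valid, s0=s0, rsq=rsq, kind=kind)


def summarize_region(
    pmap: ParameterMap, labels: np.ndarray, region_ids, region_names=None
) -> list[RegionSummary]:
    """Mean/SD of the fitted times over valid voxels of each region.

    SD is the population (n-denominator) standard deviation.  Raises if a
    region contains no valid voxels.
    """
    if labels.shape != pmap.values_ms.shape:
        raise ValueError("label grid shape mismatch")
    region_ids = list(np.atleast_1d(region_ids))
    if region_names is None:
        region_names = [str(r) for r in region_ids]
    out = []
    for rid, name in zip(region_ids, region_names):
        m = (labels == rid) & pmap.valid
        if not m.any():
            raise ValueError(f"region {name} has no valid voxels")
        vals = pmap.values_ms[m]
        out.append(
            RegionSummary(
                region=name,
                mean_ms=float(vals.mean()),
                sd_ms=float(vals.std()),
                n_voxels=int(m.sum()),
            )
        )
    return out
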