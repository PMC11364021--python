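"""Maximum-likelihood combination of independent SAXS measurements.

Independent measurements of the same particle differ by an arbitrary
multiplicative scale (concentration, calibration) and an additive constant
(solvent-subtraction uncertainty).  The consensus procedure iterates:

1. *Align*: the current reference curve is linearly interpolated onto each
   dataset's q grid and fitted with a linear function a * I_ref + b by
   weighted least squares (weights 1/sigma^2; reference errors are not
   used).  Each dataset is brought onto the reference scale as
   I_align = (I - b)/a, sigma_align = sigma/a.
2. *Combine*: datapoints are assigned to bins of a predefined (linear or
   logarithmic) q array and merged by inverse-variance maximum likelihood:
   with w_i = sigma_i^-2, per bin j over its M_j points
   I_j = sum(w I)/sum(w), sigma_j = sum(w)^(-1/2), q_j = sum(w q)/sum(w).
   Empty bins are dropped.
3. *Normalize*: divide by the mean of the first five points (or by the
   Guinier I(0)) so that I(0) ~ 1, then shift so the minimum intensity
   equals a small floor (default 0.001).
4. *Iterate* with the combined curve as the new reference until the
   per-dataset alignment chi^2 values converge, which makes the result
   independent of the choice of reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sas_io import SASProfile

log = logging.getLogger(__name__)


@dataclass
class AlignmentResult:
    """Scale/offset alignment of one dataset to a reference curve."""

    a: float
    b: float
    chi2: float      # reduced, M - 2 degrees of freedom
    M: int


@dataclass
class BinningSpec:
    """Target q array for the combination step."""

    mode: str = "log"
    n_bins: int = 501
    q_lo: float | None = None
    q_hi: float | None = None

    def __post_init__(self):
        if self.mode not in ("log", "linear"):
            raise ValueError("mode must be 'log' or 'linear'")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def edges(self, q_lo: float | None = None, q_hi: float | None = None):
        """Bin edges; half-open [edge_j, edge_{j+1}), last edge inclusive."""
        lo = self.q_lo if self.q_lo is not None else q_lo
        hi = self.q_hi if self.q_hi is not None else q_hi
        if lo is None or hi is None or not lo < hi:
            raise ValueError("binning range undefined or degenerate")
        if self.mode == "log":
            if lo <= 0:
                raise ValueError("log binning requires q_lo > 0")
            return np.geomspace(lo, hi, self.n_bins + 1)
        return np.linspace(lo, hi, self.n_bins + 1)


@dataclass
class PerInputDiagnostics:
    label: str
    alignment: AlignmentResult
    chi2: float                  # reduced chi^2 vs consensus, expt sigma only
    residuals: np.ndarray        # (I - a I_cons - b)/sigma on the input grid
    q: np.ndarray                # q values of the residual series


@dataclass
class ConsensusResult:
    """Combined profile with per-input alignment and goodness diagnostics."""

    profile: SASProfile
    per_input: list
    n_iterations: int
    converged: bool
    binning: BinningSpec
    chi2_trace: list = field(default_factory=list)

    @property
    def mean_chi2(self) -> float:
        return float(np.mean([p.chi2 for p in self.per_input]))

    @property
    def max_chi2(self) -> float:
        return float(np.max([p.chi2 for p in self.per_input]))


def truncate_qmin(profile: SASProfile, q_min: float) -> SASProfile:
    """Drop points below the per-dataset inclusion q_min.

    Used to exclude batch-data Guinier regions affected by aggregation or
    interparticle interference; the cut is recorded in the metadata.
    """
    if q_min <= profile.q[0]:
        return profile
    keep = profile.q >= q_min
    if keep.sum() < 3:
        raise ValueError(f"q_min = {q_min} leaves fewer than 3 points")
    meta = dict(profile.meta)
    meta["q_min_truncated"] = f"{q_min:g}"
    return SASProfile(q=profile.q[keep], I=profile.I[keep],
                      sigma=profile.sigma[keep], label=profile.label,
                      mode=profile.mode, meta=meta)


def _overlap_interp(reference: SASProfile, target: SASProfile):
    """Interpolate the reference onto the target q grid over its coverage.

    For combined curves the coverage is the outer edges of the occupied
    bins (recorded by :func:`combine_ml`): bin membership is then stable
    under the iteration, whereas the weighted-mean q of the end bins moves
    slightly as alignments update.  Interpolation is clamped (constant) over
    the sub-bin margin beyond the outermost weighted-mean q; elsewhere it is
    strictly inside the reference range.
    """
    lo = float(reference.meta.get("coverage_lo", reference.q[0]))
    hi = float(reference.meta.get("coverage_hi", reference.q[-1]))
    inside = (target.q >= lo) & (target.q <= hi)
    i_ref = np.interp(target.q[inside], reference.q, reference.I)
    return inside, i_ref


def align_pair(reference: SASProfile, target: SASProfile) -> AlignmentResult:
    """Fit a * I_ref + b to the target over the shared q range.

    Weighted least squares with target weights 1/sigma^2; the reduced chi^2
    uses M - 2 degrees of freedom.  Reference uncertainties are not used.
    """
    if not target.has_sigma:
        raise ValueError(f"{target.label}: no sigma column; cannot align")
    inside, i_ref = _overlap_interp(reference, target)
    m = int(inside.sum())
    if m < 3:
        raise ValueError("insufficient q overlap (need >= 3 points)")
    y = target.I[inside]
    w = 1.0 / target.sigma[inside] ** 2
    sw, sx, sy = w.sum(), (w * i_ref).sum(), (w * y).sum()
    sxx, sxy = (w * i_ref * i_ref).sum(), (w * i_ref * y).sum()
    det = sw * sxx - sx * sx
    if abs(det) < 1e-300 * max(sw * sxx, 1.0) or det == 0.0:
        raise ValueError("singular alignment (constant reference curve)")
    a = (sw * sxy - sx * sy) / det
    b = (sxx * sy - sx * sxy) / det
    chi2 = float((w * (y - a * i_ref - b) ** 2).sum() / (m - 2))
    return AlignmentResult(a=float(a), b=float(b), chi2=chi2, M=m)


def apply_alignment(profile: SASProfile, a: float, b: float) -> SASProfile:
    """Bring a dataset onto the reference scale: (I - b)/a, sigma/a."""
    if a <= 0:
        raise ValueError("non-positive scale factor a; pathological input")
    return profile.copy(I=(profile.I - b) / a, sigma=profile.sigma / a)


def combine_ml(aligned_profiles, binning: BinningSpec,
               return_assignment: bool = False):
    """Inverse-variance merge of aligned datasets on a predefined q array.

    Per bin j: I_j = sum(w I)/sum(w), sigma_j = sum(w)^(-1/2) and
    q_j = sum(w q)/sum(w) over the M_j assigned points; empty bins are
    dropped, so the output has at most ``binning.n_bins`` points.
    """
    qs = np.concatenate([p.q for p in aligned_profiles])
    is_ = np.concatenate([p.I for p in aligned_profiles])
    sig = np.concatenate([p.sigma for p in aligned_profiles])
    if np.any(~(sig > 0)):
        raise ValueError("combination requires sigma > 0")
    edges = binning.edges(qs.min(), qs.max())
    nb = edges.size - 1
    idx = np.searchsorted(edges, qs, side="right") - 1
    idx[qs == edges[-1]] = nb - 1          # last edge inclusive
    valid = (idx >= 0) & (idx < nb)
    if not valid.any():
        raise ValueError("all bins empty (disjoint q ranges)")
    idx, qs, is_, sig = idx[valid], qs[valid], is_[valid], sig[valid]
    w = 1.0 / sig ** 2
    sw = np.bincount(idx, weights=w, minlength=nb)
    occupied = sw > 0
    swi = np.bincount(idx, weights=w * is_, minlength=nb)[occupied]
    swq = np.bincount(idx, weights=w * qs, minlength=nb)[occupied]
    sw = sw[occupied]
    occ_idx = np.flatnonzero(occupied)
    out = SASProfile(q=swq / sw, I=swi / sw, sigma=sw ** -0.5,
                     label="combined", mode="consensus",
                     meta={"n_inputs": str(len(aligned_profiles)),
                           "binning": binning.mode,
                           "coverage_lo": f"{edges[occ_idx[0]]:.12e}",
                           "coverage_hi": f"{edges[occ_idx[-1] + 1]:.12e}"})
    if return_assignment:
        return out, edges, idx, occupied
    return out


def normalize_forward(profile: SASProfile, method: str = "first5",
                      floor: float = 0.001) -> SASProfile:
    """Scale so I(0) ~ 1, then shift so min(I) equals ``floor``.

    ``first5`` divides by the mean of the first five points; ``guinier``
    divides by the Guinier-extrapolated I(0).  Errors are scaled by the same
    factor; the shift does not affect them.  Output is unitless.
    """
    if method == "first5":
        if profile.n_points < 5:
            raise ValueError("first-five normalization needs >= 5 points")
        scale = float(profile.I[:5].mean())
    elif method == "guinier":
        from .profile_fitting import guinier_fit
        scale = guinier_fit(profile, policy="fixed_limit").i0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if scale <= 0:
        raise ValueError("non-positive normalization divisor")
    intensity = profile.I / scale
    shift = floor - intensity.min()
    meta = dict(profile.meta)
    meta.update(norm_scale=f"{scale:.9e}", norm_shift=f"{shift:.9e}")
    return profile.copy(I=intensity + shift, sigma=profile.sigma / scale,
                        meta=meta)


def run_consensus(profiles, binning: BinningSpec | None = None,
                  reference: SASProfile | None = None,
                  norm_method: str = "first5", floor: float = 0.001,
                  tol: float = 1e-6, max_iter: int = 200) -> ConsensusResult:
    """Iterative align-combine-normalize consensus of >= 2 measurements.

    Convergence: the maximum over inputs of the relative change of the
    alignment chi^2 between successive iterations drops below ``tol``.
    Non-convergence is flagged on the result, not raised.  The per-input
    chi^2 values against the final consensus use the experimental errors
    only, not those of the combined curve.
    """
    profiles = list(profiles)
    usable = [p for p in profiles if p.has_sigma]
    if len(usable) < 2:
        raise ValueError("need at least 2 profiles with sigma > 0")
    if len(usable) < len(profiles):
        log.warning("dropped %d profiles without sigma",
                    len(profiles) - len(usable))
    binning = binning or BinningSpec()
    ref = reference if reference is not None else usable[0]
    prev_chi2 = None
    chi2_trace = []
    converged = False
    alignments = None
    combined = None
    for iteration in range(1, max_iter + 1):
        alignments = [align_pair(ref, p) for p in usable]
        aligned = [apply_alignment(p, al.a, al.b)
                   for p, al in zip(usable, alignments)]
        combined = normalize_forward(combine_ml(aligned, binning),
                                     method=norm_method, floor=floor)
        chi2 = np.array([al.chi2 for al in alignments])
        chi2_trace.append(chi2.copy())
        log.debug("consensus iteration %d: mean chi2 %.6g", iteration,
                  chi2.mean())
        if prev_chi2 is not None:
            rel = np.abs(chi2 - prev_chi2) / np.maximum(chi2, 1e-6)
            if rel.max() < tol:
                converged = True
                break
        prev_chi2 = chi2
        ref = combined
    per_input = []
    for p in usable:
        al = align_pair(combined, p)
        inside, i_cons = _overlap_interp(combined, p)
        resid = (p.I[inside] - al.a * i_cons - al.b) / p.sigma[inside]
        chi2 = float((resid ** 2).sum() / max(inside.sum() - 2, 1))
        per_input.append(PerInputDiagnostics(
            label=p.label, alignment=al, chi2=chi2, residuals=resid,
            q=p.q[inside]))
    return ConsensusResult(profile=combined, per_input=per_input,
                           n_iterations=len(chi2_trace), converged=converged,
                           binning=binning, chi2_trace=chi2_trace)


def empirical_error_check(profiles_on_common_grid) -> np.ndarray:
    """Calibration ratio of scatter across inputs to the propagated error.

    Inputs must be aligned and re-gridded to a common q scale.  Per q the
    sample standard deviation across the K inputs is divided by
    sqrt(K) * sigma_combined, where sigma_combined is the propagated
    inverse-variance error of their merge.  Well-calibrated errors give a
    mean ratio near 1; errors understated by a factor f give ~f.
    """
    profiles = list(profiles_on_common_grid)
    k = len(profiles)
    if k < 3:
        raise ValueError("need >= 3 profiles")
    q0 = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q0.shape or not np.allclose(p.q, q0):
            raise ValueError("profiles must share a common q grid")
    intensity = np.array([p.I for p in profiles])
    w = 1.0 / np.array([p.sigma for p in profiles]) ** 2
    sd = intensity.std(axis=0, ddof=1)
    sigma_combined = w.sum(axis=0) ** -0.5
    return sd / (np.sqrt(k) * sigma_combined)
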