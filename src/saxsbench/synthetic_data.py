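"""Synthetic inputs for exercising the pipeline without downloads.

Three families of synthetic data are generated here:

* noisy *replicas* of a known truth profile with per-dataset scales,
  offsets and heterogeneous q grids, emulating independent measurements of
  one particle on different instruments (SEC vs batch coverage);
* *pseudo-experimental mixtures* of an oligomer with a larger contaminant
  (e.g. a tetramer with a dimer of tetramers), built from predicted
  profiles, an experimental-style error template and Gaussian noise;
* *analytic-oracle structures* (bead spheres, compact globules) whose
  scattering has a closed form or is cheap to verify.

All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sas_io import AtomicModel, SASProfile

# group frequencies of a typical globular protein's heavy atoms, used for
# pseudo-protein globules (roughly backbone + average side-chain content)
_GLOBULE_GROUPS = ("C", "CH", "CH2", "CH3", "N", "NH", "NH2", "O", "OH", "S")
_GLOBULE_WEIGHTS = (0.17, 0.17, 0.22, 0.08, 0.02, 0.14, 0.03, 0.13, 0.03, 0.01)


@dataclass
class MixtureSpec:
    """Components and mass fractions of a pseudo-experimental mixture.

    ``orders`` are the oligomeric orders j of each component relative to the
    reference particle: at equal mass concentration a j-mer contributes
    per-mass forward scattering proportional to j, so per-particle profiles
    are divided by j before mass-fraction averaging ('proportionate
    scaling').  The alternative number-fraction convention is obtained with
    orders of 1.
    """

    components: list                      # [(SASProfile, mass_fraction), ...]
    orders: list | None = None
    error_template: SASProfile | None = None
    noise_seed: int | None = None

    def __post_init__(self):
        fracs = np.array([f for _, f in self.components], float)
        if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("mass fractions must be >= 0 and sum to 1")
        if self.orders is None:
            self.orders = [1.0] * len(self.components)
        if len(self.orders) != len(self.components):
            raise ValueError("orders length mismatch")


@dataclass
class ReplicaSpec:
    """K noisy replicas of a truth profile with known scales and offsets."""

    truth: SASProfile
    K: int
    scales: np.ndarray | None = None      # a_k > 0
    offsets: np.ndarray | None = None     # b_k
    rel_sigma: float = 0.01               # constant-fraction sigma model
    sigma_floor_frac: float = 0.02        # sigma floor as fraction of I(0)
    error_template: SASProfile | None = None
    q_jitter: float = 0.0                 # fractional grid-spacing jitter
    q_subrange: list | None = None        # per-replica (q_lo, q_hi) or None
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.scales is None:
            self.scales = np.ones(self.K)
        if self.offsets is None:
            self.offsets = np.zeros(self.K)
        self.scales = np.asarray(self.scales, float)
        self.offsets = np.asarray(self.offsets, float)
        if self.scales.size != self.K or self.offsets.size != self.K:
            raise ValueError("scales/offsets length must equal K")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")


def make_oligomer(model: AtomicModel, copies: int = 2,
                  displacement: float = 60.0, axis=(1.0, 0.0, 0.0),
                  rotations: list | None = None,
                  min_contact: float = 1.0) -> AtomicModel:
    """Rigid oligomer of translated (optionally rotated) copies.

    Copies are placed at k * displacement along ``axis``; an error is raised
    if any inter-copy atom pair comes closer than ``min_contact`` (steric
    overlap).  ``copies = 1`` returns a plain copy.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    parts = []
    for k in range(copies):
        rot = None if rotations is None else rotations[k]
        parts.append(model.transformed(rotation=rot,
                                       translation=k * displacement * axis))
    for a in range(len(parts)):
        for b in range(a + 1, len(parts)):
            d, _ = cKDTree(parts[a].coords).query(parts[b].coords, k=1)
            if d.min() < min_contact:
                raise ValueError("steric overlap between oligomer copies "
                                 f"(min distance {d.min():.2f} A)")
    out = parts[0]
    out.coords = np.concatenate([p.coords for p in parts])
    for name in ("element", "group", "radius", "h_count", "s"):
        setattr(out, name, np.concatenate([getattr(p, name) for p in parts]))
    for name in ("res_name", "atom_name"):
        vals = [getattr(p, name) for p in parts]
        setattr(out, name, None if vals[0] is None else np.concatenate(vals))
    out.label = f"{model.label} x{copies}"
    return out


def mix_profiles(spec: MixtureSpec) -> SASProfile:
    """Mass-fraction average of proportionately scaled component profiles.

    Components are interpolated onto the first component's q grid, divided
    by their oligomeric order (equal-mass-concentration convention) and
    averaged with the given fractions; errors propagate in quadrature.  If
    the spec carries an error template and seed, template errors and
    Gaussian noise are applied to the result via :func:`add_noise`.
    """
    base, _ = spec.components[0]
    q = base.q
    intensity = np.zeros_like(q)
    var = np.zeros_like(q)
    for (profile, frac), order in zip(spec.components, spec.orders):
        yi = np.interp(q, profile.q, profile.I)
        si = np.interp(q, profile.q, np.nan_to_num(profile.sigma))
        intensity += frac * yi / order
        var += (frac * si / order) ** 2
    out = SASProfile(q=q.copy(), I=intensity, sigma=np.sqrt(var),
                     label="mixture", mode="model",
                     meta={"fractions": ",".join(
                         f"{f:g}" for _, f in spec.components)})
    if spec.error_template is not None:
        if spec.noise_seed is None:
            raise ValueError("noise_seed required with an error template")
        out = add_noise(out, spec.error_template, spec.noise_seed)
    return out


def add_noise(profile: SASProfile, template: SASProfile,
              seed: int) -> SASProfile:
    """Apply an experimental-style error template plus Gaussian noise.

    The template's sigma(q) is interpolated onto the profile grid and
    rescaled to the profile's intensity scale (ratio of the first-five-point
    means), the intensities are perturbed by independent Gaussian draws of
    those sigmas, and the sigma column is set accordingly.  Deterministic
    under a fixed seed.
    """
    sigma = np.interp(profile.q, template.q, template.sigma)
    scale = profile.I[:5].mean() / template.I[:5].mean()
    sigma = sigma * scale
    rng = np.random.default_rng(seed)
    noisy = profile.I + rng.standard_normal(profile.n_points) * sigma
    mode = profile.mode if profile.mode in ("sec", "batch") else "batch"
    if np.all(sigma > 0):
        return profile.copy(I=noisy, sigma=sigma, mode=mode)
    # zero-sigma template: identity on I; keep model mode (sigma = 0 legal)
    return profile.copy(I=noisy, sigma=sigma, mode="model")


def make_replicas(spec: ReplicaSpec) -> list:
    """K replicas a_k * truth + b_k with noise and optional distinct grids."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for k in range(spec.K):
        q = spec.truth.q.copy()
        if spec.q_subrange is not None and spec.q_subrange[k] is not None:
            lo, hi = spec.q_subrange[k]
            q = q[(q >= lo) & (q <= hi)]
        if spec.q_jitter > 0:
            dq = np.gradient(q)
            q = np.sort(q + rng.uniform(-1, 1, q.size) * spec.q_jitter * dq)
        clean = spec.scales[k] * np.interp(q, spec.truth.q, spec.truth.I)
        intensity = clean + spec.offsets[k]
        if spec.error_template is not None:
            sigma = np.interp(q, spec.error_template.q,
                              spec.error_template.sigma)
            sigma = sigma * spec.scales[k]
        else:
            # counting-statistics-like: proportional to the signal before the
            # background offset, with a floor so sigma never vanishes
            sigma = spec.rel_sigma * (np.abs(clean)
                                      + spec.sigma_floor_frac * np.abs(clean[0]))
        noisy = intensity + rng.standard_normal(q.size) * sigma
        if np.all(sigma > 0):
            out.append(SASProfile(q=q, I=noisy, sigma=sigma,
                                  label=f"replica-{k}", mode="batch"))
        else:   # noiseless degenerate case: keep as model-mode truth copy
            out.append(SASProfile(q=q, I=noisy, sigma=sigma,
                                  label=f"replica-{k}", mode="model"))
    return out


def synthetic_error_template(n_points: int = 301, q_max: float = 0.5,
                             q_min: float = 0.01, sigma0: float = 0.01,
                             decay: float = 0.15,
                             floor_frac: float = 0.1) -> SASProfile:
    """Experimental-style error profile: sigma decreasing from a low-q maximum.

    sigma(q) = sigma0 * (floor_frac + (1 - floor_frac) exp(-q/decay)),
    paired with a smooth Gaussian-like intensity column (I(0) = 1) used only
    to carry the intensity scale for rescaling.
    """
    q = np.linspace(q_min, q_max, n_points)
    sigma = sigma0 * (floor_frac + (1 - floor_frac) * np.exp(-q / decay))
    intensity = np.exp(-(q * 20.0) ** 2 / 3.0)
    return SASProfile(q=q, I=intensity, sigma=sigma, label="error-template",
                      mode="model")


def make_bead_sphere(radius: float = 20.0, spacing: float = 2.0,
                     label: str = "bead-sphere") -> np.ndarray:
    """Coordinates of a dense cubic-lattice filling of a sphere [A].

    Returns raw coordinates (constant-form-factor scatterers) for use with
    :func:`saxsbench.profile_predictor.debye_sum` analytic oracles.
    """
    n = int(np.ceil(radius / spacing))
    axis = spacing * np.arange(-n, n + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    return pts[(pts ** 2).sum(axis=1) <= radius ** 2]


def make_globule(n_atoms: int = 120, radius: float = 12.0, seed: int = 0,
                 min_dist: float = 1.5, label: str = "globule") -> AtomicModel:
    """Compact pseudo-protein globule with realistic group composition.

    Atoms are placed uniformly in a sphere with a minimum-distance rejection
    rule (loosely mimicking atomic packing) and assigned united-atom groups
    drawn from typical protein heavy-atom frequencies.  Deterministic for a
    fixed seed; SASA fractions are left unset.
    """
    rng = np.random.default_rng(seed)
    coords = []
    attempts = 0
    while len(coords) < n_atoms and attempts < 200 * n_atoms:
        attempts += 1
        p = rng.uniform(-radius, radius, 3)
        if (p ** 2).sum() > radius ** 2:
            continue
        if coords:
            d2 = ((np.asarray(coords) - p) ** 2).sum(axis=1)
            if d2.min() < min_dist ** 2:
                continue
        coords.append(p)
    if len(coords) < n_atoms:
        raise ValueError("could not place atoms; lower n_atoms or min_dist")
    groups = rng.choice(_GLOBULE_GROUPS, size=n_atoms, p=_GLOBULE_WEIGHTS)
    return AtomicModel.from_groups(np.asarray(coords), groups, label=label)


# the contamination-series mass fractions of the pseudo-experimental
# mixture experiment (percent contaminant)
CONTAMINATION_RAMP = (0.0, 1.0, 2.0, 2.5, 3.0, 4.0, 5.0, 10.0)


def contamination_series(pure: SASProfile, contaminant: SASProfile,
                         template: SASProfile, seed: int,
                         percents=CONTAMINATION_RAMP,
                         orders=(1, 2)) -> list:
    """Pseudo-experimental mixtures with increasing contaminant fraction.

    Experimental-style errors and Gaussian noise are applied once to each
    predicted component profile (seed and seed + 1), after which the noisy
    components are proportionately scaled and mass-fraction averaged with
    error propagation.  Returns [(percent, SASProfile), ...]; the 0% entry
    is the pure noisy component.
    """
    noisy_pure = add_noise(pure, template, seed)
    noisy_cont = add_noise(contaminant, template, seed + 1)
    out = []
    for pct in percents:
        f = pct / 100.0
        spec = MixtureSpec(components=[(noisy_pure, 1.0 - f),
                                       (noisy_cont, f)], orders=list(orders))
        mixed = mix_profiles(spec)
        out.append((pct, mixed.copy(mode="batch",
                                    label=f"mixture-{pct:g}pct")))
    return out
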