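"""Free-energy surfaces, transition-path statistics, diffusion/MFPT inference
and temperature reweighting along rotation coordinates.

Free energies are stored in units of k_B T at the profile's stated
temperature (``F = -ln P`` plus an offset placing the minimum at zero); the
temperature itself is carried in reduced energy units (k_B T in r.u.) so
profiles can be converted and reweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar


class LandscapeError(ValueError):
    """Raised for invalid landscape-analysis input."""


@dataclass
class FreeEnergyProfile:
    """Binned free energy over one or two collective coordinates.

    ``values`` holds F in k_B T (NaN on empty bins, minimum offset to zero);
    ``counts`` are raw (or effective, for reweighted profiles) samples per
    bin; ``temperature`` is k_B T in reduced energy units.
    """

    bin_edges: list[np.ndarray]
    values: np.ndarray
    counts: np.ndarray
    temperature: float

    def __post_init__(self):
        self.bin_edges = [np.asarray(e, dtype=float) for e in self.bin_edges]
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        occupied = self.counts > 0
        if not np.all(np.isfinite(self.values[occupied])):
            raise LandscapeError("non-finite free energy on occupied bins")
        if np.any(self.counts < 0):
            raise LandscapeError("negative bin counts")

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)

    def centers(self, dim: int = 0) -> np.ndarray:
        e = self.bin_edges[dim]
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class StateDefinition:
    """Coordinate windows defining the unrotated and rotated ensembles.

    Defaults are the rotation-angle windows (degrees) used for the yeast
    ribosome ensembles.
    """

    unrotated: tuple[float, float] = (-1.12, 0.82)
    rotated: tuple[float, float] = (5.4, 7.86)

    def __post_init__(self):
        for name in ("unrotated", "rotated"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise LandscapeError(f"{name} window must have lo < hi")
        lo_u, hi_u = self.unrotated
        lo_r, hi_r = self.rotated
        if max(lo_u, lo_r) < min(hi_u, hi_r):
            raise LandscapeError("state windows overlap")

    def in_unrotated(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) > self.unrotated[0]) & (np.asarray(x) < self.unrotated[1])

    def in_rotated(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) > self.rotated[0]) & (np.asarray(x) < self.rotated[1])


@dataclass
class TransitionPathStats:
    """Per-bin transition-path probability and the path segments."""

    bin_edges: np.ndarray
    p_tp: np.ndarray
    counts: np.ndarray
    segments: list[tuple[int, int]]
    n_transitions: int
    peak_value: float
    peak_position: float


@dataclass
class DiffusionModel:
    """Coordinate-space diffusion coefficient ((coordinate units)^2 / tau_ru)."""

    D: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.D <= 0:
            raise LandscapeError("D must be positive")


# --- free-energy estimation -------------------------------------------------


def free_energy(
    samples: np.ndarray,
    bins,
    temperature: float = 1.0,
    weights: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Histogram-based free energy ``F = -ln P`` (in k_B T), minimum at zero.

    ``samples`` is (n,) for 1D or (n, d) for d-dimensional profiles; empty
    bins are NaN, not zero.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
        if not np.isscalar(bins) and np.ndim(bins) == 1:
            bins = [np.asarray(bins)]  # a plain edge array for the 1D case
    if len(samples) == 0:
        raise LandscapeError("no samples")
    counts, edges = np.histogramdd(samples, bins=bins, weights=weights)
    total = counts.sum()
    if total <= 0:
        raise LandscapeError("all sample weights are zero")
    with np.errstate(divide="ignore"):
        values = -np.log(counts / total)
    values[counts == 0] = np.nan
    values = values - np.nanmin(values)
    return FreeEnergyProfile(
        bin_edges=list(edges), values=values, counts=counts, temperature=temperature
    )


# --- transition-path analysis -----------------------------------------------


def _state_labels(series: np.ndarray, states: StateDefinition) -> np.ndarray:
    labels = np.full(len(series), -1, dtype=np.int8)
    labels[states.in_unrotated(series)] = 0
    labels[states.in_rotated(series)] = 1
    return labels


def _fill_forward(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    last = -1
    for k in range(len(labels)):
        if labels[k] != -1:
            last = labels[k]
        out[k] = last
    return out


def transition_path_probability(
    series: np.ndarray,
    states: StateDefinition,
    bins=40,
    min_samples_per_bin: int = 50,
) -> TransitionPathStats:
    """P(TP | coordinate bin): the chance that a visit to a bin lies on a
    transition path.

    A frame is on a transition path iff it lies strictly between the last
    exit from one state window and the next entry into the *other* window
    (excursions returning to the origin state do not count).  For diffusive
    dynamics on a good coordinate, the peak approaches the diffusion-limited
    value of 0.5.  The peak is reported over bins holding at least
    ``min_samples_per_bin`` frames.
    """
    series = np.asarray(series, dtype=float)
    labels = _state_labels(series, states)
    prev = _fill_forward(labels)
    nxt = _fill_forward(labels[::-1])[::-1]
    tp_mask = (labels == -1) & (prev != -1) & (nxt != -1) & (prev != nxt)

    visited = labels[labels != -1]
    n_transitions = int(np.sum(visited[1:] != visited[:-1])) if len(visited) > 1 else 0

    counts, edges = np.histogram(series, bins=bins)
    tp_counts, _ = np.histogram(series[tp_mask], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_tp = np.where(counts > 0, tp_counts / np.maximum(counts, 1), np.nan)

    segments: list[tuple[int, int]] = []
    in_seg = False
    for k, flag in enumerate(tp_mask):
        if flag and not in_seg:
            start, in_seg = k, True
        elif not flag and in_seg:
            segments.append((start, k - 1))
            in_seg = False
    if in_seg:
        segments.append((start, len(tp_mask) - 1))

    eligible = counts >= max(min_samples_per_bin, 1)
    if np.any(eligible & np.isfinite(p_tp)):
        masked = np.where(eligible, p_tp, -np.inf)
        peak_idx = int(np.nanargmax(masked))
        peak_value = float(p_tp[peak_idx])
        peak_position = float(0.5 * (edges[peak_idx] + edges[peak_idx + 1]))
    else:
        peak_value, peak_position = 0.0, float("nan")

    return TransitionPathStats(
        bin_edges=edges, p_tp=p_tp, counts=counts, segments=segments,
        n_transitions=n_transitions, peak_value=peak_value, peak_position=peak_position,
    )


# --- diffusion inference ----------------------------------------------------


def infer_diffusion(
    series: np.ndarray,
    profile: FreeEnergyProfile,
    lag: float,
    frame_interval: float,
    d_bounds: tuple[float, float] = (1e-8, 1e4),
) -> DiffusionModel:
    """Maximum-posterior uniform diffusion coefficient along a 1D coordinate.

    The coordinate is discretized on the profile's bins and modeled as a
    nearest-neighbor jump process (discretized Smoluchowski equation) whose
    rates are set by the supplied free energy and a single D:
    ``k(i -> i+/-1) = D / dx^2 * exp(-(F_dest - F_src) / 2)`` (F in k_B T).
    The likelihood of the observed bin-to-bin transitions at the requested
    lag is maximized over log D.
    """
    if profile.ndim != 1:
        raise LandscapeError("diffusion inference requires a 1D profile")
    if lag < frame_interval:
        raise LandscapeError("lag must be at least one frame interval")
    series = np.asarray(series, dtype=float)
    edges = profile.bin_edges[0]
    occupied = np.nonzero(profile.counts > 0)[0]
    lo_bin, hi_bin = occupied.min(), occupied.max()
    f = profile.values[lo_bin : hi_bin + 1]
    if np.any(~np.isfinite(f)):
        raise LandscapeError("empty bins inside the sampled range; use coarser bins")
    n_bins = len(f)
    dx = float(edges[1] - edges[0])

    lag_frames = int(round(lag / frame_interval))
    assign = np.clip(np.digitize(series, edges) - 1 - lo_bin, 0, n_bins - 1)
    src = assign[:-lag_frames]
    dst = assign[lag_frames:]
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (src, dst), 1.0)
    if np.sum(counts) - np.trace(counts) < 10:
        raise LandscapeError(
            "too few inter-bin transitions at this lag; increase the lag or coarsen bins"
        )

    lag_time = lag_frames * frame_interval
    up = np.exp(-0.5 * np.diff(f))      # i -> i+1
    down = np.exp(0.5 * np.diff(f))     # i+1 -> i

    def neg_loglik(log_d: float) -> float:
        d = np.exp(log_d)
        rate = d / dx**2
        gen = np.zeros((n_bins, n_bins))
        idx = np.arange(n_bins - 1)
        gen[idx + 1, idx] = rate * up
        gen[idx, idx + 1] = rate * down
        gen[np.arange(n_bins), np.arange(n_bins)] = -gen.sum(axis=0)
        prop = expm(gen * lag_time)
        prob = np.clip(prop.T, 1e-300, None)  # prob[src, dst]
        return -float(np.sum(counts * np.log(prob)))

    res = minimize_scalar(
        neg_loglik,
        bounds=(np.log(d_bounds[0]), np.log(d_bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    d_hat = float(np.exp(res.x))
    return DiffusionModel(
        D=d_hat,
        diagnostics={
            "neg_loglik": float(res.fun),
            "lag": lag_time,
            "n_transitions": float(np.sum(counts) - np.trace(counts)),
            "n_bins": n_bins,
        },
    )


# --- mean first-passage time ------------------------------------------------


def mfpt_from_profile(
    profile: FreeEnergyProfile,
    diffusion: DiffusionModel,
    rho_initial: float,
    rho_final: float,
    rho_min: float,
    n_grid: int = 2000,
    variant: str = "outer",
) -> float:
    """Mean first-passage time (tau_ru) by nested quadrature over the profile.

    Evaluates ``<tau> = int_{rho_initial}^{rho_final} drho
    int_{rho_min}^{rho} drho' exp[F(rho) - F(rho')] / D`` with F in k_B T.
    ``variant="outer"`` divides the outer integrand by D(rho) as printed in
    the source relation; ``variant="inner"`` uses the textbook placement of
    D(rho') inside the inner integral (identical for uniform D).
    """
    if profile.ndim != 1:
        raise LandscapeError("MFPT requires a 1D profile")
    if variant not in ("outer", "inner"):
        raise LandscapeError("variant must be 'outer' or 'inner'")
    centers = profile.centers()
    finite = np.isfinite(profile.values)
    lo = min(rho_min, rho_initial)
    hi = rho_final
    inside = (centers >= lo) & (centers <= hi)
    if np.any(inside & ~finite):
        raise LandscapeError(
            "empty bins inside the integration range; re-bin or interpolate first"
        )
    known_x = centers[finite]
    known_f = profile.values[finite]
    if len(known_x) < 2:
        raise LandscapeError("profile too sparse for quadrature")

    grid = np.linspace(lo, hi, n_grid)
    f_grid = np.interp(grid, known_x, known_f)
    d = diffusion.D

    inner_integrand = np.exp(-f_grid)
    if variant == "inner":
        inner_integrand = inner_integrand / d
    inner = np.concatenate(
        [[0.0], np.cumsum(0.5 * (inner_integrand[1:] + inner_integrand[:-1]) * np.diff(grid))]
    )
    outer_integrand = np.exp(f_grid) * inner
    if variant == "outer":
        outer_integrand = outer_integrand / d
    mask = grid >= rho_initial
    og, ov = grid[mask], outer_integrand[mask]
    return float(np.trapezoid(ov, og))


def rate_from_barrier(delta_f_kbt: float, attempt_frequency: float) -> float:
    """Mean barrier-crossing time ``tau = exp(dF / k_B T) / C``."""
    if attempt_frequency <= 0:
        raise LandscapeError("attempt frequency must be positive")
    return float(np.exp(delta_f_kbt) / attempt_frequency)


def contact_strength_perturbation(
    n_unique_contacts: float = 500.0,
    mean_weight_ru: float = 0.2,
    fractional_increase: float = 0.02,
    kbt_per_ru: float = 2.0,
) -> float:
    """Endpoint stabilization (k_B T) from scaling unique-contact strengths.

    A fractional increase of the unique-contact weights stabilizes each
    endpoint by ``n * w * fraction`` reduced units, i.e.
    ``n * w * fraction * (k_B T per r.u.)`` in thermal units.
    """
    return n_unique_contacts * mean_weight_ru * fractional_increase * kbt_per_ru


# --- temperature reweighting ------------------------------------------------


def fep_weights(
    potential_energy: np.ndarray, t0: float, t_prime: float
) -> tuple[np.ndarray, float]:
    """Per-frame reweighting factors ``W = exp[-(1/T' - 1/T0) U]`` and ESS.

    Temperatures are k_B T in reduced energy units; U is the per-frame
    potential energy in reduced units.  The maximum exponent is subtracted
    before exponentiation, so the weights are defined up to normalization.
    Returns ``(weights, effective_sample_size)``.
    """
    u = np.asarray(potential_energy, dtype=float)
    if np.any(~np.isfinite(u)):
        raise LandscapeError("non-finite potential energies")
    exponent = -(1.0 / t_prime - 1.0 / t0) * u
    weights = np.exp(exponent - exponent.max())
    ess = float(weights.sum() ** 2 / np.sum(weights**2))
    return weights, ess


def fep_reweight(
    series: np.ndarray,
    potential_energy: np.ndarray,
    t0: float,
    t_prime: float,
    bins,
    max_fraction: float = 0.02,
    force: bool = False,
    ess_warn_fraction: float = 0.1,
) -> tuple[FreeEnergyProfile, dict]:
    """Free-energy profile at a nearby temperature by reweighting.

    Refuses |T' - T0|/T0 beyond ``max_fraction`` (default 2%) unless
    ``force``; at T' = T0 the weights are identically 1 and the profile
    equals the direct histogram estimate.  Returns the profile and a
    diagnostics dict including the effective sample size.
    """
    series = np.asarray(series, dtype=float)
    u = np.asarray(potential_energy, dtype=float)
    if len(series) != len(u):
        raise LandscapeError("series and potential energies differ in length")
    rel = abs(t_prime - t0) / t0
    if rel > max_fraction + 1e-12 and not force:
        raise LandscapeError(
            f"|T' - T0|/T0 = {rel:.3f} exceeds the {max_fraction:.0%} perturbation "
            "bound; pass force=True to override"
        )
    weights, ess = fep_weights(u, t0, t_prime)
    profile = free_energy(series, bins=bins, temperature=t_prime, weights=weights)
    diagnostics = {"ess": ess, "n_frames": len(series), "relative_shift": rel}
    diagnostics["ess_ok"] = ess >= ess_warn_fraction * len(series)
    return profile, diagnostics


def delta_f_ensembles(
    series: np.ndarray,
    states: StateDefinition,
    weights: np.ndarray | None = None,
    n_blocks: int = 10,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> tuple[float, float]:
    """``dF = F_rot - F_unrot = ln(P_unrot / P_rot)`` in k_B T, with a
    block-bootstrap error bar.

    Frames are split into ``n_blocks`` contiguous blocks that are resampled
    with replacement, which respects the correlation time of the series.
    """
    series = np.asarray(series, dtype=float)
    w = np.ones(len(series)) if weights is None else np.asarray(weights, dtype=float)
    in_u = states.in_unrotated(series)
    in_r = states.in_rotated(series)
    p_u, p_r = float(w[in_u].sum()), float(w[in_r].sum())
    if p_u <= 0 or p_r <= 0:
        raise LandscapeError("an ensemble window holds no (weighted) samples")
    delta_f = float(np.log(p_u / p_r))

    block_edges = np.linspace(0, len(series), n_blocks + 1, dtype=int)
    blocks = [(block_edges[k], block_edges[k + 1]) for k in range(n_blocks)]
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_bootstrap):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        pu = pr = 0.0
        for b in chosen:
            lo, hi = blocks[b]
            pu += w[lo:hi][in_u[lo:hi]].sum()
            pr += w[lo:hi][in_r[lo:hi]].sum()
        if pu > 0 and pr > 0:
            estimates.append(np.log(pu / pr))
    err = float(np.std(estimates)) if estimates else float("nan")
    return delta_f, err
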