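"""Drift fields on the circle and Fokker-Planck propagation.

A memory evolves by the Langevin equation ``dtheta = beta*G(theta) dt + sigma dW``
on the circle.  The drift landscape G is a linear combination of von Mises
derivative bumps whose centers are one circular standard deviation apart
(spacing 2*pi/12 by default).  The associated Fokker-Planck equation

    dp/dt = -d[beta*G(theta) p]/dtheta + (sigma^2/2) d^2p/dtheta^2

is solved on a periodic grid with an exponentially fitted (Scharfetter-Gummel)
finite-volume discretization.  Its rate matrix is a Markov generator, so the
matrix-exponential propagator conserves mass, preserves positivity and
satisfies the semigroup property exactly; there is no explicit time step and
hence no CFL stability constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import special

from .wheel import TWO_PI, wrap_angle

DEFAULT_SPACING = TWO_PI / 12
DEFAULT_GRID_SIZE = 128


def kappa_from_circular_sd(sd: float) -> float:
    """Von Mises concentration whose circular SD equals ``sd``.

    Inverts R = exp(-sd^2/2) through A(kappa) = I1(kappa)/I0(kappa) with
    Newton iterations from the Best-Fisher starting approximations.
    """
    rbar = float(np.exp(-0.5 * sd * sd))
    return solve_kappa(rbar)


def solve_kappa(rbar: float, tol: float = 1e-12, max_iter: int = 100, cap: float = 1e4) -> float:
    """Invert the Bessel ratio A(kappa) = I1/I0 = rbar (von Mises MLE)."""
    if rbar <= 0:
        return 0.0
    if rbar >= 1:
        return cap
    # Best & Fisher starting values
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    for _ in range(max_iter):
        a = special.i1e(k) / special.i0e(k)
        # d A/d kappa = 1 - A/kappa - A^2
        da = 1 - a / k - a * a if k > 0 else 0.5
        step = (a - rbar) / da
        k -= step
        if k <= 0:
            k = 1e-8
        if abs(step) < tol * max(1.0, k):
            break
    return min(k, cap)


def vm_derivative(theta, mu: float, kappa: float):
    """Derivative of the von Mises density with respect to angle."""
    theta = np.asarray(theta, dtype=float)
    z = np.cos(theta - mu)
    norm = TWO_PI * special.i0e(kappa)
    return -kappa * np.sin(theta - mu) * np.exp(kappa * (z - 1.0)) / norm


def build_basis(
    spacing: float = DEFAULT_SPACING,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Von Mises derivative basis evaluated on the grid, (grid_size, n_basis).

    Centers sit at ``k*spacing``; the concentration is chosen so the circular
    SD of each bump equals the spacing ("separated by one standard
    deviation").  Columns are normalized to unit Euclidean norm on the grid.
    ``spacing`` must divide 2*pi.
    """
    n_basis = TWO_PI / spacing
    if abs(n_basis - round(n_basis)) > 1e-9:
        raise ValueError(f"spacing {spacing} does not divide 2*pi")
    n_basis = int(round(n_basis))
    kappa = kappa_from_circular_sd(spacing)
    grid = np.arange(grid_size) * (TWO_PI / grid_size)
    cols = [vm_derivative(grid, k * spacing, kappa) for k in range(n_basis)]
    basis = np.stack(cols, axis=1)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


@dataclass
class DriftField:
    """Drift landscape G(theta) as weights on the von Mises derivative basis."""

    weights: np.ndarray
    spacing: float = DEFAULT_SPACING
    grid_size: int = DEFAULT_GRID_SIZE
    _kappa: float = field(init=False, repr=False)
    _norms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n_basis = int(round(TWO_PI / self.spacing))
        if self.weights.shape != (n_basis,):
            raise ValueError(f"expected {n_basis} weights, got {self.weights.shape}")
        self._kappa = kappa_from_circular_sd(self.spacing)
        grid = np.arange(self.grid_size) * (TWO_PI / self.grid_size)
        cols = np.stack(
            [vm_derivative(grid, k * self.spacing, self._kappa) for k in range(n_basis)], axis=1
        )
        self._norms = np.linalg.norm(cols, axis=0)

    @property
    def n_basis(self) -> int:
        return len(self.weights)

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_size) * (TWO_PI / self.grid_size)

    def __call__(self, theta):
        """Evaluate G at any angle via the analytic basis expansion."""
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta, dtype=float)
        for k, (w, nrm) in enumerate(zip(self.weights, self._norms)):
            if w != 0.0:
                out = out + (w / nrm) * vm_derivative(theta, k * self.spacing, self._kappa)
        return out

    def on_grid(self) -> np.ndarray:
        return self.__call__(self.grid)

    def normalized(self) -> tuple["DriftField", float]:
        """Rescale so max|G| = 1 on a dense grid; returns (field, scale).

        The Langevin gain beta and the drift-weight norm are jointly
        unidentifiable; reporting uses this normalization with beta carrying
        all gain.
        """
        dense = wrap_angle(np.linspace(0, TWO_PI, 4096, endpoint=False))
        scale = float(np.max(np.abs(self.__call__(dense))))
        if scale == 0:
            return DriftField(self.weights.copy(), self.spacing, self.grid_size), 0.0
        return DriftField(self.weights / scale, self.spacing, self.grid_size), scale


def project_on_basis(func, spacing: float = DEFAULT_SPACING, grid_size: int = DEFAULT_GRID_SIZE) -> DriftField:
    """Least-squares projection of an arbitrary periodic function onto the basis."""
    basis = build_basis(spacing, grid_size)
    grid = np.arange(grid_size) * (TWO_PI / grid_size)
    w, *_ = np.linalg.lstsq(basis, np.asarray(func(grid), dtype=float), rcond=None)
    return DriftField(w, spacing, grid_size)


@dataclass
class ProbabilityField:
    """Probability density over the periodic angular grid at a given time."""

    p: np.ndarray
    grid: np.ndarray
    time: float = 0.0

    @property
    def step(self) -> float:
        return TWO_PI / len(self.grid)

    def mass(self) -> float:
        return float(np.sum(self.p) * self.step)

    def mean_abs_deviation(self, reference: float) -> float:
        """Mean absolute circular deviation of the density from ``reference``."""
        d = np.abs(np.angle(np.exp(1j * (self.grid - reference))))
        return float(np.sum(d * self.p) * self.step)

    def interp(self, theta):
        """Periodic linear interpolation of the density at arbitrary angles."""
        x = wrap_angle(np.asarray(theta, dtype=float)) / self.step
        i0 = np.floor(x).astype(int) % len(self.p)
        frac = x - np.floor(x)
        i1 = (i0 + 1) % len(self.p)
        return self.p[i0] * (1 - frac) + self.p[i1] * frac


def delta_density(theta0: float, grid_size: int = DEFAULT_GRID_SIZE) -> ProbabilityField:
    """Unit mass concentrated in the grid cell containing ``theta0``."""
    grid = np.arange(grid_size) * (TWO_PI / grid_size)
    h = TWO_PI / grid_size
    p = np.zeros(grid_size)
    i = int(np.floor(wrap_angle(theta0) / h + 0.5)) % grid_size
    p[i] = 1.0 / h
    return ProbabilityField(p, grid, 0.0)


def uniform_density(grid_size: int = DEFAULT_GRID_SIZE) -> ProbabilityField:
    grid = np.arange(grid_size) * (TWO_PI / grid_size)
    return ProbabilityField(np.full(grid_size, 1.0 / TWO_PI), grid, 0.0)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the Scharfetter-Gummel flux weight."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - x[small] / 2.0
    xs = np.clip(x[~small], -700, 700)
    out[~small] = xs / np.expm1(xs)
    return out


def generator_matrix(
    field: DriftField | None,
    beta: float,
    sigma: float,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Markov generator of the discretized Fokker-Planck operator.

    Acts on per-cell masses; columns sum to zero and off-diagonal rates are
    non-negative, so expm(L*t) is a stochastic matrix.  With sigma = 0 the
    exponential fitting degenerates to pure upwind advection.
    """
    h = TWO_PI / grid_size
    edges = (np.arange(grid_size) + 0.5) * h  # edge i sits between cells i and i+1
    v = beta * field(edges) if (field is not None and beta != 0.0) else np.zeros(grid_size)
    d = 0.5 * sigma * sigma
    if d > 0:
        w = v * h / d
        up = (d / h**2) * _bernoulli(-w)  # rate cell i -> i+1 across edge i
        down = (d / h**2) * _bernoulli(w)  # rate cell i+1 -> i across edge i
    else:
        up = np.maximum(v, 0.0) / h
        down = np.maximum(-v, 0.0) / h
    L = np.zeros((grid_size, grid_size))
    i = np.arange(grid_size)
    j = (i + 1) % grid_size
    L[j, i] += up
    L[i, i] -= up
    L[i, j] += down
    L[j, j] -= down
    return L


def transition_matrix(
    field: DriftField | None,
    beta: float,
    sigma: float,
    duration_s: float,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Stochastic matrix mapping initial cell masses to masses after ``duration_s``."""
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if duration_s == 0 or (sigma == 0 and (beta == 0 or field is None)):
        return np.eye(grid_size)
    L = generator_matrix(field, beta, sigma, grid_size)
    return sla.expm(L * duration_s)


def propagate(
    p0: ProbabilityField,
    field: DriftField | None,
    beta: float,
    sigma: float,
    duration_s: float,
) -> ProbabilityField:
    """Evolve a density under drift beta*G and diffusion sigma for ``duration_s`` seconds."""
    n = len(p0.p)
    T = transition_matrix(field, beta, sigma, duration_s, n)
    h = p0.step
    m = T @ (p0.p * h)
    p = np.clip(m, 0.0, None) / h
    return ProbabilityField(p, p0.grid, p0.time + duration_s)


def bin_masses(pf: ProbabilityField, n_bins: int) -> np.ndarray:
    """Aggregate a density's cell masses onto a coarser centered binning.

    The fine grid must be an odd multiple of ``n_bins`` so that coarse bin
    edges align with fine cell edges; bin b collects the fine cells centered
    nearest to ``b * 2pi/n_bins``.  Used to compare high-resolution solutions
    against sample histograms.
    """
    n = len(pf.p)
    if n % n_bins:
        raise ValueError("grid size must be a multiple of n_bins")
    r = n // n_bins
    if r % 2 == 0:
        raise ValueError("refinement ratio must be odd for edge alignment")
    m = pf.p * pf.step
    half = r // 2
    idx = (np.arange(n_bins)[:, None] * r + np.arange(-half, half + 1)[None, :]) % n
    return m[idx].sum(axis=1)


def wrapped_normal_density(grid: np.ndarray, mu: float, variance: float, n_wraps: int = 20) -> np.ndarray:
    """Closed-form wrapped normal density (diffusion-only oracle)."""
    k = np.arange(-n_wraps, n_wraps + 1)
    d = grid[:, None] - mu + TWO_PI * k[None, :]
    return np.sum(np.exp(-0.5 * d * d / variance), axis=1) / np.sqrt(TWO_PI * variance)


@dataclass
class AttractorSet:
    """Zero crossings of the effective drift beta*G, classified by slope."""

    attractor_angles: np.ndarray
    repeller_angles: np.ndarray

    @property
    def count(self) -> int:
        return len(self.attractor_angles)


def find_attractors(field: DriftField, beta: float, n_scan: int = 8192) -> AttractorSet:
    """Locate attractors (negative-slope zeros) and repellers of beta*G.

    Scans a dense grid for sign changes and refines each root by linear
    interpolation.  ``beta = 0`` yields an empty set by definition.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0 (sign lives in the drift weights)")
    if beta == 0:
        return AttractorSet(np.array([]), np.array([]))
    theta = np.arange(n_scan) * (TWO_PI / n_scan)
    g = beta * field(theta)
    if np.allclose(g, 0.0, atol=1e-12):
        return AttractorSet(np.array([]), np.array([]))
    g_next = np.roll(g, -1)
    cross = np.nonzero(np.sign(g) * np.sign(g_next) < 0)[0]
    roots, slopes = [], []
    h = TWO_PI / n_scan
    for i in cross:
        t = g[i] / (g[i] - g_next[i])
        roots.append(wrap_angle(theta[i] + t * h))
        slopes.append((g_next[i] - g[i]) / h)
    roots = np.array(roots)
    slopes = np.array(slopes)
    order = np.argsort(roots)
    roots, slopes = roots[order], slopes[order]
    return AttractorSet(roots[slopes < 0], roots[slopes > 0])
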