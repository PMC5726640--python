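"""A small Cartesian minimizer and Metropolis annealer.

This is not a re-implementation of a production annealing protocol (no
torsion-angle dynamics, no restraint energies, no cooling stages); it is the
smallest engine that can demonstrate the hydrogen flip-trap: under
heavy-atom-only chirality impropers a mirror-flipped ring hydrogen sits in a
genuine local minimum separated from the correct position by a bond-energy
barrier, so minimization and annealing leave it flipped; under four-vertex
impropers the flipped state is energetically wrong and the same runs recover
the correct chirality.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

from .chirality import ChiralityViolation, check_chirality
from .energetics import TermList, energy, energy_and_gradient


class AnnealError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule in energy units (kcal/mol scale)."""

    t_high: float = 50.0
    t_low: float = 0.5
    n_steps: int = 5000
    step_sigma: float = 0.05      # A
    seed: int = 20171212

    def __post_init__(self) -> None:
        if not (self.t_high >= self.t_low > 0):
            raise ValueError("need t_high >= t_low > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.step_sigma <= 0:
            raise ValueError("step_sigma must be > 0")

    def temperatures(self) -> np.ndarray:
        if self.n_steps == 0:
            return np.zeros(0)
        if self.n_steps == 1 or self.t_high == self.t_low:
            return np.full(self.n_steps, self.t_high)
        ratio = (self.t_low / self.t_high) ** (1.0 / (self.n_steps - 1))
        return self.t_high * ratio ** np.arange(self.n_steps)


def minimize(coords: np.ndarray, terms: TermList, *,
             max_iter: int = 20000, gtol: float = 1e-6) -> np.ndarray:
    """Steepest descent with Armijo backtracking.

    Steps always go along the negative gradient; the trial step length is
    the Barzilai-Borwein estimate (plain fixed-step descent zig-zags badly
    between the stiff bond terms and the soft torsions), backtracked until
    the Armijo condition holds, so energy never increases across accepted
    steps.  Stops when the gradient norm falls below ``gtol`` or after
    ``max_iter`` iterations.  Raises :class:`AnnealError` on divergence.
    """
    x = np.array(coords, float, copy=True)
    e, g = energy_and_gradient(x, terms)
    etot = e.total
    step = 1e-4
    x_prev = None
    g_prev = None
    for _ in range(max_iter):
        gsq = float(np.dot(g.ravel(), g.ravel()))
        if math.sqrt(gsq) <= gtol:
            break
        # Barzilai-Borwein step length as the first Armijo trial; it kills
        # the zig-zag that plain fixed-step descent suffers on stiff terms
        if x_prev is not None:
            s = (x - x_prev).ravel()
            y = (g - g_prev).ravel()
            sy = float(np.dot(s, y))
            if sy > 1e-300:
                step = float(np.dot(s, s)) / sy
        alpha = min(max(step, 1e-12), 1.0)
        accepted = False
        for _ in range(50):
            trial = x - alpha * g
            e_t = energy(trial, terms).total
            if not np.isfinite(e_t):
                raise AnnealError("energy diverged during minimization")
            if e_t <= etot - 1e-4 * alpha * gsq:     # Armijo along -g
                x_prev, g_prev = x, g
                x = trial
                etot = e_t
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        _, g = energy_and_gradient(x, terms)
    return x


@dataclass
class AnnealResult:
    coords: np.ndarray
    energies: np.ndarray          # energy after every step
    acceptance_ratio: float


def anneal(coords: np.ndarray, terms: TermList,
           schedule: AnnealSchedule) -> AnnealResult:
    """Metropolis sampling with single-atom Gaussian displacement proposals
    under geometric cooling.  Bit-for-bit reproducible for a fixed
    (seed, schedule)."""
    rng = np.random.default_rng(schedule.seed)
    x = np.array(coords, float, copy=True)
    n = x.shape[0]
    etot = energy(x, terms).total
    temps = schedule.temperatures()
    energies = np.empty(len(temps))
    accepted = 0
    for s, T in enumerate(temps):
        i = int(rng.integers(n))
        move = rng.normal(scale=schedule.step_sigma, size=3)
        x[i] += move
        e_new = energy(x, terms).total
        dE = e_new - etot
        if dE <= 0 or rng.random() < np.exp(-dE / T):
            etot = e_new
            accepted += 1
        else:
            x[i] -= move
        energies[s] = etot
    ratio = accepted / len(temps) if len(temps) else 0.0
    return AnnealResult(x, energies, ratio)


# ---------------------------------------------------------------------------
# the flip-trap demonstration
# ---------------------------------------------------------------------------

@dataclass
class FlipTrapReport:
    mode: str
    initial_violations: list[ChiralityViolation]
    final_violations: list[ChiralityViolation]
    final_gradient_norm: float
    trajectory_energies: np.ndarray
    scan_t: np.ndarray            # H position parameter, -1 (flipped) .. +1 (ideal)
    scan_energy: np.ndarray
    barrier: float                # max interior scan energy minus max endpoint energy
    final_coords: np.ndarray = field(repr=False, default=None)


def hydrogen_line_scan(bundle, terms: TermList, center_name: str = "C3",
                       hydrogen_name: str = "H3", n_points: int = 201):
    """Energy profile moving the hydrogen along the line through the carbon
    between the flipped (-1) and ideal (+1) positions; under heavy-atom-only
    impropers its interior maximum is the wall that traps the flip."""
    names = [a.name for a in bundle.molecule.atoms]
    c = names.index(center_name)
    h = names.index(hydrogen_name)
    ref = bundle.reference_conformation
    u = ref[h] - ref[c]
    t = np.linspace(-1.0, 1.0, n_points)
    energies = np.empty(n_points)
    x = np.array(ref, copy=True)
    for k, tk in enumerate(t):
        if abs(tk) < 1e-9:
            tk = 1e-6               # avoid H exactly on top of C
        x[h] = ref[c] + tk * u
        energies[k] = energy(x, terms).total
    return t, energies


def demo_flip_trap(mode: str = "heavy_only", seed: int = 0, *,
                   use_anneal: bool = False,
                   schedule: AnnealSchedule | None = None) -> FlipTrapReport:
    """Start the schematic pyranose with H3 reflected through C3 and relax.

    ``heavy_only``: chirality impropers see no hydrogen, minimization
    converges with the flip still present.  ``four_vertex``: the improper
    over the four substituents penalizes the flip and the run ends with
    correct chirality.  Violations are always judged geometrically against
    the four-vertex reference targets.
    """
    from .fixtures import make_pyranose

    if mode not in ("heavy_only", "four_vertex"):
        raise ValueError(f"unknown improper mode {mode!r}")
    bundle = make_pyranose(seed)
    terms = bundle.terms(mode)
    names = [a.name for a in bundle.molecule.atoms]
    start = bundle.variants["flipped_H3"]
    initial = check_chirality(start, bundle.centers, atom_names=names)

    if use_anneal:
        sched = schedule or AnnealSchedule(seed=seed, n_steps=3000)
        res = anneal(start, terms, sched)
        x = minimize(res.coords, terms, max_iter=3000)
        energies = res.energies
    else:
        x = minimize(start, terms, max_iter=4000)
        energies = np.array([energy(start, terms).total, energy(x, terms).total])

    final = check_chirality(x, bundle.centers, atom_names=names)
    gnorm = float(np.linalg.norm(energy_and_gradient(x, terms)[1]))
    t, scan = hydrogen_line_scan(bundle, terms)
    interior = scan[1:-1].max()
    barrier = float(interior - max(scan[0], scan[-1]))
    return FlipTrapReport(mode, initial, final, gnorm, energies, t, scan,
                          barrier, x)
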