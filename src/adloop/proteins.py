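"""Heterodimer dynamics of amyloid-beta and hyperphosphorylated tau.

Each region carries four concentrations: healthy and toxic amyloid-beta
(``Ab``, ``Abt``) and tau (``T``, ``Tt``).  Healthy protein is produced and
cleared; it converts to the toxic isoform on contact with existing toxic
protein (the prion-like templating step); toxic protein is cleared more
slowly and diffuses along white-matter tracts.  Two couplings close the
loop with neural activity through the hyperactivity factor ``q_ha``:
it scales amyloid production and biases the diffusion of toxic tau toward
hyperactive regions.  A synergy term converts healthy tau to toxic tau
faster where toxic amyloid is present.

Concentrations are in M, time in years.  Diffusion uses the Laplacian of
the length-scaled weights (``rho`` is a transport speed in cm/yr; dividing
the max-normalized weights by tract length in cm yields rates in 1/yr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import solve_ivp

from .connectome import Connectome, diffusion_laplacian

__all__ = [
    "ProteinParams",
    "ProteinState",
    "SeedingSpec",
    "ProteinTrajectory",
    "build_seeding",
    "initialize_proteins",
    "heterodimer_derivatives",
    "integrate_proteinopathy",
    "ABETA_SEED_AMOUNT",
    "TAU_SEED_AMOUNT",
]

#: Initial toxic concentrations placed at the seed regions (M).
ABETA_SEED_AMOUNT = 0.0125
TAU_SEED_AMOUNT = 0.0025

STRATEGIES = ("fixed", "abeta_random", "tau_random", "both_random",
              "abeta_anterior", "abeta_posterior")


@dataclass
class ProteinParams:
    """Kinetic constants (defaults are the model's standard values).

    Units: production M/yr; clearance 1/yr; transformation 1/(M yr);
    synergy 1/(M^2 yr); rho cm/yr.
    """

    prod_ab: float = 3.0
    clear_ab: float = 3.0
    trans_ab: float = 3.0
    clear_abt: float = 2.4
    prod_t: float = 3.0
    clear_t: float = 3.0
    trans_t: float = 3.0
    clear_tt: float = 2.55
    syn: float = 0.4
    rho: float = 50.0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if not val > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ProteinState:
    """Per-region concentrations (M) of the four protein pools."""

    ab: np.ndarray
    abt: np.ndarray
    t: np.ndarray
    tt: np.ndarray

    def __post_init__(self):
        self.ab, self.abt, self.t, self.tt = (
            np.atleast_1d(np.asarray(x, float))
            for x in (self.ab, self.abt, self.t, self.tt))
        if min(self.ab.min(), self.abt.min(), self.t.min(),
               self.tt.min()) < 0:
            raise ValueError("negative concentrations")

    @property
    def n(self) -> int:
        return self.ab.size

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.ab, self.abt, self.t, self.tt])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ProteinState":
        parts = np.split(np.asarray(vec, float), 4)
        return cls(*parts)

    def copy(self) -> "ProteinState":
        return ProteinState(self.ab.copy(), self.abt.copy(),
                            self.t.copy(), self.tt.copy())


@dataclass
class SeedingSpec:
    """Which regions receive the initial toxic deposits, and how much."""

    strategy: str
    abeta_regions: np.ndarray
    tau_regions: np.ndarray
    abeta_amount: float = ABETA_SEED_AMOUNT
    tau_amount: float = TAU_SEED_AMOUNT

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.abeta_regions = np.asarray(self.abeta_regions, dtype=int)
        self.tau_regions = np.asarray(self.tau_regions, dtype=int)


def _seed_pairs(con: Connectome, flag: str) -> list[tuple[int, int]]:
    pairs = con.homolog_pairs()
    return [(l, r) for l, r in pairs if getattr(con.regions[l], flag)]


def build_seeding(con: Connectome, strategy: str = "fixed",
                  rng_seed: int = 0) -> SeedingSpec:
    """Construct a seeding specification for a connectome.

    ``fixed`` seeds exactly the annotated regions (six bilateral amyloid
    pairs, the entorhinal-homolog tau pair).  The randomized variants draw
    hemisphere-symmetric pairs uniformly without replacement, preserving the
    fixed pair counts; ``abeta_anterior`` / ``abeta_posterior`` restrict the
    amyloid draw to pairs whose ``ap_class`` matches (tau stays fixed).
    Deterministic given ``rng_seed``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not con.regions:
        raise ValueError("connectome has no annotations")
    rng = np.random.default_rng(rng_seed)
    pairs = con.homolog_pairs()
    ab_fixed = _seed_pairs(con, "abeta_seed")
    tau_fixed = _seed_pairs(con, "tau_seed")

    def draw(eligible: list[tuple[int, int]], k: int, what: str):
        if len(eligible) < k:
            raise ValueError(
                f"only {len(eligible)} eligible pairs for {what}, "
                f"need {k}")
        idx = rng.choice(len(eligible), size=k, replace=False)
        return [eligible[i] for i in sorted(idx)]

    ab_pairs, tau_pairs = ab_fixed, tau_fixed
    if strategy in ("abeta_random", "both_random"):
        ab_pairs = draw(pairs, len(ab_fixed), "amyloid seeding")
    elif strategy in ("abeta_anterior", "abeta_posterior"):
        cls = strategy.split("_")[1]
        eligible = [(l, r) for l, r in pairs
                    if con.regions[l].ap_class == cls]
        ab_pairs = draw(eligible, len(ab_fixed),
                        f"{cls} amyloid seeding")
    if strategy in ("tau_random", "both_random"):
        tau_pairs = draw(pairs, len(tau_fixed), "tau seeding")

    return SeedingSpec(
        strategy=strategy,
        abeta_regions=np.array(sorted(i for p in ab_pairs for i in p)),
        tau_regions=np.array(sorted(i for p in tau_pairs for i in p)),
    )


def initialize_proteins(con: Connectome, seeding: SeedingSpec,
                        params: ProteinParams | None = None) -> ProteinState:
    """Healthy pools at the homogeneous equilibrium (production/clearance),
    toxic pools zero except at the seeds."""
    params = params or ProteinParams()
    n = con.n
    ab = np.full(n, params.prod_ab / params.clear_ab)
    t = np.full(n, params.prod_t / params.clear_t)
    abt = np.zeros(n)
    tt = np.zeros(n)
    abt[seeding.abeta_regions] = seeding.abeta_amount
    tt[seeding.tau_regions] = seeding.tau_amount
    return ProteinState(ab, abt, t, tt)


def heterodimer_derivatives(state: ProteinState, params: ProteinParams,
                            laplacian: np.ndarray,
                            qha: np.ndarray | float = 1.0) -> ProteinState:
    """Time derivatives of the four protein pools.

    The hyperactivity factor ``qha`` multiplies amyloid production and the
    whole toxic-tau Laplacian term; the synergy term drains healthy tau into
    the toxic pool where toxic amyloid is present.  ``laplacian`` must be
    built from the current (possibly tau-damaged) weights.
    """
    ab, abt, t, tt = state.ab, state.abt, state.t, state.tt
    qha = np.broadcast_to(np.asarray(qha, float), ab.shape)
    L = np.asarray(laplacian, float)
    p = params
    syn_flux = p.syn * abt * t * tt
    d_ab = -p.rho * (L @ ab) + p.prod_ab * qha - p.clear_ab * ab \
        - p.trans_ab * ab * abt
    d_abt = -p.rho * (L @ abt) - p.clear_abt * abt + p.trans_ab * ab * abt
    d_t = -p.rho * (L @ t) + p.prod_t - p.clear_t * t \
        - p.trans_t * t * tt - syn_flux
    d_tt = -p.rho * (L @ tt) * qha - p.clear_tt * tt \
        + p.trans_t * t * tt + syn_flux
    return _raw_state(d_ab, d_abt, d_t, d_tt)


def _raw_state(ab, abt, t, tt) -> ProteinState:
    """Build a ProteinState without the non-negativity check (derivatives
    may legitimately be negative)."""
    obj = ProteinState.__new__(ProteinState)
    obj.ab, obj.abt, obj.t, obj.tt = (np.atleast_1d(np.asarray(x, float))
                                      for x in (ab, abt, t, tt))
    return obj


@dataclass
class ProteinTrajectory:
    """Concentrations recorded at every protein step.

    ``states`` has shape (n_times, n_regions, 4) ordered (Ab, Abt, T, Tt).
    """

    times: np.ndarray
    states: np.ndarray
    region_names: list[str] = field(default_factory=list)

    @property
    def tt(self) -> np.ndarray:
        """Toxic-tau concentrations, shape (n_times, n_regions)."""
        return self.states[:, :, 3]

    @property
    def abt(self) -> np.ndarray:
        return self.states[:, :, 1]

    def final_state(self) -> ProteinState:
        s = self.states[-1]
        return ProteinState(s[:, 0], s[:, 1], s[:, 2], s[:, 3])

    def to_frame(self):
        """Tidy DataFrame: (year, region, Ab, Abt, T, Tt)."""
        import pandas as pd

        nt, n, _ = self.states.shape
        names = self.region_names or [f"region_{i}" for i in range(n)]
        return pd.DataFrame({
            "year": np.repeat(self.times, n),
            "region": names * nt,
            "Ab": self.states[:, :, 0].ravel(),
            "Abt": self.states[:, :, 1].ravel(),
            "T": self.states[:, :, 2].ravel(),
            "Tt": self.states[:, :, 3].ravel(),
        })


def _step_interval(rhs, y0: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Advance an ODE system over one exchange interval with adaptive RK45."""
    sol = solve_ivp(rhs, (t0, t1), y0, method="RK45",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"protein integration failed: {sol.message}")
    return sol.y[:, -1]


def integrate_proteinopathy(
    state: ProteinState,
    params: ProteinParams,
    laplacian_provider,
    qha: np.ndarray | float = 1.0,
    t_span_years: tuple[float, float] = (0.0, 40.0),
    dt_years: float = 0.25,
    region_names: list[str] | None = None,
) -> ProteinTrajectory:
    """Integrate the heterodimer model alone (fixed neural feedback).

    ``laplacian_provider`` is either a constant Laplacian matrix or a
    callable ``t -> L`` yielding the current operator (weights may decay
    over the disease course).  The state is recorded every ``dt_years``;
    within each recording interval the ODEs are advanced adaptively.
    Negative undershoots are clipped to zero with a warning.
    """
    if callable(laplacian_provider):
        lap = laplacian_provider
    else:
        L_const = np.asarray(laplacian_provider, float)
        def lap(_t):
            return L_const

    t0, t1 = t_span_years
    n_steps = int(round((t1 - t0) / dt_years))
    times = t0 + dt_years * np.arange(n_steps + 1)
    n = state.n
    out = np.empty((n_steps + 1, n, 4))
    cur = state.copy()
    out[0] = np.stack([cur.ab, cur.abt, cur.t, cur.tt], axis=1)
    clipped = False

    def rhs(t, y):
        s = ProteinState.from_vector(np.maximum(y, 0.0))
        return heterodimer_derivatives(s, params, lap(t), qha).as_vector()

    vec = cur.as_vector()
    for k in range(n_steps):
        vec = _step_interval(rhs, vec, times[k], times[k + 1])
        if not np.all(np.isfinite(vec)):
            raise RuntimeError(
                f"non-finite protein state at year {times[k + 1]:.2f}")
        if np.any(vec < 0):
            if np.min(vec) < -1e-9:
                clipped = True
            vec = np.maximum(vec, 0.0)
        out[k + 1] = vec.reshape(4, n).T
    if clipped:
        warnings.warn("negative concentration undershoot clipped to zero")
    return ProteinTrajectory(times=times, states=out,
                             region_names=region_names or [])


def connectome_laplacian_provider(con: Connectome):
    """Provider for a static connectome: length-scaled diffusion Laplacian."""
    L = diffusion_laplacian(con.weights, con.lengths)
    return lambda _t: L
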