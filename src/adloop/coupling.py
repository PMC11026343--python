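"""Closed-loop coupling between proteinopathy and neural dynamics.

Toxic protein load accumulates into bounded damage variables (``q_abt``,
``q_tt`` in [0, 1)), which relax the Jansen-Rit parameters toward their
disease limits: ``He`` rises toward ``he_max`` under amyloid damage,
``Cip`` falls toward ``cip_min`` under both proteins, ``Cep`` falls toward
``cep_min`` under tau damage, and interregional weights decay toward
``w0 * (1 - sc_dam)`` at a rate set by the tau damage of both endpoints.
In the opposite direction, the regional firing rate measured from the
brain-network model feeds a hyperactivity damage variable ``q_ha`` (Eq.
style: rate ratio against a proteinopathy-free baseline) that scales
amyloid production and toxic-tau diffusion.

Two timescales coexist: protein/damage/parameter ODEs advance in 0.25-year
exchange steps; the brain-network model is re-evaluated every simulated
year (10 s of activity, first 2 s discarded) to refresh the firing-rate
ratio, which is held constant in between.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .connectome import Connectome, diffusion_laplacian
from .neural import (JRGlobalParams, JRRegionalParams, integrate_network,
                     regional_firing_rate)
from .proteins import (ProteinParams, ProteinState, SeedingSpec,
                       build_seeding, initialize_proteins, _raw_state,
                       heterodimer_derivatives, _step_interval)
from . import metrics as _metrics

__all__ = [
    "DamageParams",
    "DamageState",
    "ClosedLoopConfig",
    "DiseaseTrajectory",
    "damage_derivatives",
    "hyperactivity_damage_derivative",
    "parameter_derivatives",
    "run_closed_loop",
]


@dataclass
class DamageParams:
    """Damage rates, transfer constants and parameter-change limits."""

    cq_abt: float = 1.0      # 1/(M yr), amyloid damage rate
    cq_tt: float = 1.0       # 1/(M yr), tau damage rate
    cq_ha: float = 0.01      # hyperactivity damage rate
    cexc_abt: float = 0.8    # 1/yr, amyloid -> He
    cinh_abt: float = 0.4    # 1/yr, amyloid -> Cip
    cexc_tt: float = 1.8     # 1/yr, tau -> Cep
    cinh_tt: float = 1.8     # 1/yr, tau -> Cip
    csc_tt: float = 0.05     # 1/yr, tau -> interregional weights
    he_max: float = 3.65     # mV, ceiling for He
    cip_min: float = 13.25   # floor for Cip
    cep_min: float = 28.0    # floor for Cep
    sc_dam: float = 0.3      # max fractional weight loss
    q_max_ha: float = 2.0    # ceiling for hyperactivity damage

    def __post_init__(self):
        if not 0.0 <= self.sc_dam <= 1.0:
            raise ValueError("sc_dam must lie in [0, 1]")


@dataclass
class DamageState:
    """Per-region damage variables."""

    q_abt: np.ndarray
    q_tt: np.ndarray
    q_ha: np.ndarray

    @classmethod
    def pristine(cls, n: int) -> "DamageState":
        # q_ha starts at its neutral value 1 (Eq. is multiplicative in q_ha,
        # so 0 would be absorbing); protein damage starts at 0.
        return cls(np.zeros(n), np.zeros(n), np.ones(n))


def damage_derivatives(q_abt, q_tt, abt, tt,
                       params: DamageParams) -> tuple[np.ndarray, np.ndarray]:
    """Saturating damage accrual ``dq/dt = c * toxic * (1 - q)``.

    Non-negative; zero iff the toxic load is zero or the damage saturated.
    """
    q_abt, q_tt = np.asarray(q_abt, float), np.asarray(q_tt, float)
    return (params.cq_abt * np.asarray(abt, float) * (1.0 - q_abt),
            params.cq_tt * np.asarray(tt, float) * (1.0 - q_tt))


def hyperactivity_damage_derivative(q_ha, delta_ha,
                                    params: DamageParams) -> np.ndarray:
    """``dq_ha/dt = cq_ha (delta_ha - q_ha)(q_max - q_ha) q_ha``.

    ``delta_ha`` is the firing-rate ratio against the proteinopathy-free
    baseline; ``q_ha = 1`` with ``delta_ha = 1`` is the neutral stationary
    point, and sustained ``delta_ha`` above ``q_max_ha`` drives ``q_ha``
    to the ceiling ``q_max_ha``.
    """
    q = np.asarray(q_ha, float)
    d = np.asarray(delta_ha, float)
    return params.cq_ha * (d - q) * (params.q_max_ha - q) * q


def parameter_derivatives(regional: JRRegionalParams, weights: np.ndarray,
                          damage: DamageState, params: DamageParams,
                          w0: np.ndarray,
                          enable_cinh_abt: bool = True,
                          enable_cinh_tt: bool = True):
    """Relaxation of the Jansen-Rit parameters toward their disease limits.

    Returns ``(dHe, dCip, dCep, dW)``.  The two inhibitory channels can be
    disabled independently to isolate the amyloid and tau contributions.
    """
    qa, qt = damage.q_abt, damage.q_tt
    d_he = params.cexc_abt * qa * (params.he_max - regional.He)
    d_cip = np.zeros_like(d_he)
    if enable_cinh_abt:
        d_cip = d_cip - params.cinh_abt * qa * (regional.Cip - params.cip_min)
    if enable_cinh_tt:
        d_cip = d_cip - params.cinh_tt * qt * (regional.Cip - params.cip_min)
    d_cep = -params.cexc_tt * qt * (regional.Cep - params.cep_min)
    w_min = w0 * (1.0 - params.sc_dam)
    d_w = -params.csc_tt * (qt[:, None] + qt[None, :]) * (weights - w_min)
    return d_he, d_cip, d_cep, d_w


@dataclass
class ClosedLoopConfig:
    """Schedule and switches for a closed-loop disease run."""

    years: float = 40.0
    dt_protein: float = 0.25          # yr, exchange/recording step
    bnm_eval_every: float = 1.0       # yr, BNM re-evaluation cadence
    bnm_duration_ms: float = 10_000.0
    bnm_discard_ms: float = 2_000.0
    neural_dt_ms: float = 1.0
    rng_seed: int = 0
    enable_cinh_abt: bool = True      # amyloid -> inhibition channel
    enable_cinh_tt: bool = True       # tau -> inhibition channel
    seeding_strategy: str = "fixed"
    plv_band: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self):
        ratio = self.bnm_eval_every / self.dt_protein
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "bnm_eval_every must be an integer multiple of dt_protein")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plv_band"] = list(d["plv_band"])
        return d


@dataclass
class DiseaseTrajectory:
    """Yearly record of a closed-loop run.

    All arrays are indexed by evaluation year (including the baseline year
    0); shapes are (Y, n) unless noted.
    """

    years: np.ndarray
    proteins: np.ndarray        # (Y, n, 4): Ab, Abt, T, Tt
    damage: np.ndarray          # (Y, n, 3): q_abt, q_tt, q_ha
    he: np.ndarray
    cip: np.ndarray
    cep: np.ndarray
    weights: np.ndarray         # (Y, n, n)
    ha: np.ndarray              # firing rate per region, ms^-1
    ha0: np.ndarray             # (n,) proteinopathy-free baseline
    peak_hz: np.ndarray
    rel_power: np.ndarray       # (Y, n, 3): delta, theta, alpha fractions
    plv: np.ndarray             # (Y, n, n) alpha-band phase locking
    mean_plv: np.ndarray        # (Y,)
    region_names: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def mean_firing_rate(self) -> np.ndarray:
        return self.ha.mean(axis=1)

    @property
    def mean_peak_hz(self) -> np.ndarray:
        return self.peak_hz.mean(axis=1)

    @property
    def mean_rel_alpha(self) -> np.ndarray:
        return self.rel_power[:, :, 2].mean(axis=1)

    def to_frame(self):
        """Tidy per-region DataFrame of scalar yearly quantities."""
        import pandas as pd

        Y, n = self.ha.shape
        names = self.region_names or [f"region_{i}" for i in range(n)]
        return pd.DataFrame({
            "year": np.repeat(self.years, n),
            "region": names * Y,
            "Ab": self.proteins[:, :, 0].ravel(),
            "Abt": self.proteins[:, :, 1].ravel(),
            "T": self.proteins[:, :, 2].ravel(),
            "Tt": self.proteins[:, :, 3].ravel(),
            "q_abt": self.damage[:, :, 0].ravel(),
            "q_tt": self.damage[:, :, 1].ravel(),
            "q_ha": self.damage[:, :, 2].ravel(),
            "He": self.he.ravel(),
            "Cip": self.cip.ravel(),
            "Cep": self.cep.ravel(),
            "firing_rate": self.ha.ravel(),
            "peak_hz": self.peak_hz.ravel(),
            "rel_delta": self.rel_power[:, :, 0].ravel(),
            "rel_theta": self.rel_power[:, :, 1].ravel(),
            "rel_alpha": self.rel_power[:, :, 2].ravel(),
        })

    def save(self, directory: str | Path) -> None:
        """Write the tidy CSV plus a JSON run manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "trajectory.csv", index=False)
        manifest = dict(config=self.config,
                        years=self.years.tolist(),
                        mean_plv=self.mean_plv.tolist())
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=1))


def _bnm_seed(rng_seed: int, year_index: int) -> np.random.SeedSequence:
    """Independent, reproducible noise stream per BNM evaluation."""
    return np.random.SeedSequence(entropy=int(rng_seed),
                                  spawn_key=(int(year_index),))


def _evaluate_bnm(con: Connectome, glob: JRGlobalParams,
                  regional: JRRegionalParams, weights: np.ndarray,
                  config: ClosedLoopConfig, year_index: int):
    rec = integrate_network(
        con, glob, regional,
        duration_ms=config.bnm_duration_ms,
        discard_ms=config.bnm_discard_ms,
        dt_ms=config.neural_dt_ms,
        rng_seed=_bnm_seed(config.rng_seed, year_index),
        weights=weights,
    )
    ha = regional_firing_rate(rec, glob.e0, glob.r, glob.v0)
    peak = np.array([_metrics.spectral_peak(rec, i)
                     for i in range(con.n)])
    rel = np.array([
        [_metrics.relative_band_power(rec, i, band)
         for band in (_metrics.DELTA, _metrics.THETA, _metrics.ALPHA)]
        for i in range(con.n)])
    fc = _metrics.plv_matrix(rec, band=config.plv_band)
    return ha, peak, rel, fc.values


def run_closed_loop(
    con: Connectome,
    config: ClosedLoopConfig | None = None,
    glob: JRGlobalParams | None = None,
    protein_params: ProteinParams | None = None,
    damage_params: DamageParams | None = None,
    seeding: SeedingSpec | None = None,
) -> DiseaseTrajectory:
    """Run the full closed-loop disease simulation.

    The schedule: (0) one proteinopathy-free BNM evaluation fixes the
    baseline firing rates ``ha0``; (1) each year, the joint protein /
    damage / parameter / weight ODE system advances in four 0.25-yr
    exchange steps (adaptively integrated within each step), then the BNM
    is re-evaluated with the current parameters and weights to refresh the
    firing-rate ratio driving ``q_ha``.  Fully deterministic given
    ``config.rng_seed``.

    Disabling the seeding (``seeding`` with empty region sets) yields a
    null run in which all year-scale states stay at their healthy values.
    """
    config = config or ClosedLoopConfig()
    glob = glob or JRGlobalParams()
    protein_params = protein_params or ProteinParams()
    damage_params = damage_params or DamageParams()
    if seeding is None:
        seeding = build_seeding(con, config.seeding_strategy,
                                rng_seed=config.rng_seed)

    n = con.n
    w0 = con.weights.copy()
    regional = JRRegionalParams().broadcast(n)
    prot = initialize_proteins(con, seeding, protein_params)
    dmg = DamageState.pristine(n)

    n_years = int(round(config.years / config.bnm_eval_every))
    steps_per_year = int(round(config.bnm_eval_every / config.dt_protein))

    # --- baseline (year 0), proteinopathy-free
    ha0, peak0, rel0, plv0 = _evaluate_bnm(
        con, glob, regional, w0, config, year_index=0)
    if np.any(ha0 < 1e-8):
        raise RuntimeError("baseline firing rate underflow; cannot form "
                           "hyperactivity ratios")
    delta_ha = np.ones(n)

    Y = n_years + 1
    rec_years = np.arange(Y) * config.bnm_eval_every
    out = DiseaseTrajectory(
        years=rec_years,
        proteins=np.empty((Y, n, 4)),
        damage=np.empty((Y, n, 3)),
        he=np.empty((Y, n)), cip=np.empty((Y, n)), cep=np.empty((Y, n)),
        weights=np.empty((Y, n, n)),
        ha=np.empty((Y, n)), ha0=ha0,
        peak_hz=np.empty((Y, n)),
        rel_power=np.empty((Y, n, 3)),
        plv=np.empty((Y, n, n)),
        mean_plv=np.empty(Y),
        region_names=con.names,
        config=config.to_dict(),
    )

    weights = w0.copy()

    def record(k, ha, peak, rel, plv):
        out.proteins[k] = np.stack([prot.ab, prot.abt, prot.t, prot.tt],
                                   axis=1)
        out.damage[k] = np.stack([dmg.q_abt, dmg.q_tt, dmg.q_ha], axis=1)
        out.he[k], out.cip[k], out.cep[k] = (regional.He, regional.Cip,
                                             regional.Cep)
        out.weights[k] = weights
        out.ha[k] = ha
        out.peak_hz[k] = peak
        out.rel_power[k] = rel
        out.plv[k] = plv
        out.mean_plv[k] = _metrics.mean_fc(plv)

    record(0, ha0, peak0, rel0, plv0)

    # flat year-scale state: 4n proteins, 3n damage, 3n params, n^2 weights
    def pack():
        return np.concatenate([
            prot.as_vector(), dmg.q_abt, dmg.q_tt, dmg.q_ha,
            regional.He, regional.Cip, regional.Cep, weights.ravel()])

    def unpack(vec):
        p = ProteinState.from_vector(np.maximum(vec[:4 * n], 0.0))
        qa = np.clip(vec[4 * n:5 * n], 0.0, 1.0)
        qt = np.clip(vec[5 * n:6 * n], 0.0, 1.0)
        qh = np.clip(vec[6 * n:7 * n], 1e-12, damage_params.q_max_ha)
        he = vec[7 * n:8 * n]
        cip = vec[8 * n:9 * n]
        cep = vec[9 * n:10 * n]
        w = vec[10 * n:].reshape(n, n)
        return p, DamageState(qa, qt, qh), JRRegionalParams(he, cip, cep), w

    clipped = False

    def rhs(_t, vec):
        p, d, reg, w = unpack(vec)
        L = diffusion_laplacian(w, con.lengths)
        dp = heterodimer_derivatives(p, protein_params, L, d.q_ha)
        dqa, dqt = damage_derivatives(d.q_abt, d.q_tt, p.abt, p.tt,
                                      damage_params)
        dqh = hyperactivity_damage_derivative(d.q_ha, delta_ha,
                                              damage_params)
        dhe, dcip, dcep, dw = parameter_derivatives(
            reg, w, d, damage_params, w0,
            enable_cinh_abt=config.enable_cinh_abt,
            enable_cinh_tt=config.enable_cinh_tt)
        return np.concatenate([dp.as_vector(), dqa, dqt, dqh,
                               dhe, dcip, dcep, dw.ravel()])

    vec = pack()
    for year in range(1, n_years + 1):
        for k in range(steps_per_year):
            t_a = (year - 1 + k * config.dt_protein) * 1.0
            vec = _step_interval(rhs, vec, t_a, t_a + config.dt_protein)
            if not np.all(np.isfinite(vec)):
                raise RuntimeError(
                    f"non-finite year-scale state in year {year}")
            if np.min(vec[:4 * n]) < -1e-9:
                clipped = True
            vec[:4 * n] = np.maximum(vec[:4 * n], 0.0)
        prot, dmg, regional, weights = unpack(vec)
        weights = np.clip(weights, w0 * (1.0 - damage_params.sc_dam), w0)
        ha, peak, rel, plv = _evaluate_bnm(
            con, glob, regional, weights, config, year_index=year)
        delta_ha = ha / ha0
        record(year, ha, peak, rel, plv)
        vec = pack()

    if clipped:
        warnings.warn("negative concentration undershoot clipped to zero")
    return out
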