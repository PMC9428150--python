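"""Bone cell population model (BCPM) of remodeling.

State variables are the concentrations (pM) of pre-osteoblasts ``Obp``,
active osteoblasts ``Oba``, pre-osteoclasts ``Ocp``, active osteoclasts
``Oca`` and osteocytes ``Ot``, plus the bone matrix fraction ``f_bm`` (% of
the representative volume element occupied by matrix).  Cell fluxes are
gated by activator/repressor Hill functions of TGF-β (released from the
matrix by resorption), of RANKL (RANK–RANKL–OPG competitive binding, with a
disease term for postmenopausal osteoporosis) and of Wnt (sclerostin-gated,
mechanoregulated).  Uncommitted osteoblast/osteoclast pools are constant.

Matrix turnover drives a tissue-age/ash-fraction histogram: new osteoid
enters at the primary ash fraction and mineralizes exponentially toward a
maximum (secondary mineralization); resorption removes average composition.
Apparent density combines matrix fraction and mean ash fraction, and the
bone density gain (BDG) is the percent change of apparent density from
treatment start.

Default constants live in ``data/bcpm_default.yaml``; they are this
package's calibrated set, built from the magnitudes of the published model
lineage, and every one of them is overridable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root


# ---------------------------------------------------------------------------
# Hill activator / repressor primitives

def hill_activator(c, K):
    """c/(c+K): fraction of receptors bound at ligand concentration c."""
    if np.any(np.asarray(K) <= 0):
        raise ValueError("Hill constant K must be > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c / (c + K)
    return float(out) if out.ndim == 0 else out


def hill_repressor(c, K):
    """K/(c+K) = 1 - activator: fraction of receptors free."""
    act = hill_activator(c, K)
    return 1.0 - act


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class BCPMParams:
    """Constants of the bone cell population model.

    Units: rates 1/day, concentrations pM, ``k_res_nom``/``k_form`` in
    percentage points of matrix fraction per day per pM of active cells,
    stresses MPa, ash fractions dimensionless.
    """

    # cell pools and rate constants
    Obu_pool: float = 1e-3
    Ocu_pool: float = 1e-3
    D_Obu: float = 0.7
    D_Obp: float = 0.35
    P_Obp: float = 0.05
    Delta_Oba: float = 0.30
    D_Ocu: float = 0.5
    D_Ocp: float = 0.2
    A_Oca_nom: float = 0.35
    eta: float = 1.0            # osteocytes per unit f_bm, pM/%
    k_res_nom: float = 7.3      # %/(pM day)
    k_form: float | None = None  # None -> balanced at the healthy steady state

    # TGF-beta (released by resorption)
    tgf_basal: float = 0.1
    tgf_per_resorption: float = 100.0   # pM per (%/day) resorbed
    K_tgf_obu: float = 0.55
    K_tgf_obp: float = 0.18
    K_tgf_ocp: float = 0.08

    # RANK-RANKL-OPG
    prl_per_obp: float = 40.0   # RANKL production per pM Obp, pM/day/pM
    d_rankl: float = 10.0       # RANKL turnover, 1/day
    opg_per_oba: float = 1000.0
    K_opg: float = 0.75
    rank_per_ocp: float = 100.0
    K_rank: float = 0.25
    K_rl_ocu: float = 6e-3
    K_rl_ocp: float = 6e-3
    pth0: float = 1.0           # constant PTH level (no PTH dosing in scope)
    K_pth_opg: float = 1.0      # PTH repression of OPG production

    # Wnt / sclerostin (mechanoregulated)
    scl0: float = 1.0
    K_scl: float = 1.0
    wnt0: float = 1.0
    K_wnt: float = 1.0
    scl_mech_exp: float = 1.0

    # mechanics
    E0_MPa: float = 84370.0
    stiff_exp_fbm: float = 2.58
    stiff_exp_ash: float = 2.74
    mech_hill_n: float = 1.0

    # mineralization
    ash_primary: float = 0.45
    ash_max: float = 0.70
    kappa_mineral: float = 8e-4  # secondary mineralization rate, 1/day
    rho_tissue_a: float = 1.41   # g/cm^3 at zero ash
    rho_tissue_b: float = 1.29   # g/cm^3 per unit ash fraction
    max_bins: int = 200

    # postmenopausal osteoporosis: sigmoidal extra RANKL production
    P_RANKL_max: float = 0.18   # pM/day
    t_onset: float = 0.0        # day
    half_time: float = 730.0    # day at 50% of max
    gamma: float = 3.0

    # microdamage stub (first-order accumulation/repair), off by default
    damage_on: bool = False
    dam_accum: float = 0.0
    dam_repair: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("k_form",) and v is None:
                continue
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        for name in ("K_tgf_obu", "K_tgf_obp", "K_tgf_ocp", "K_opg", "K_rank",
                     "K_rl_ocu", "K_rl_ocp", "K_pth_opg", "K_scl", "K_wnt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma <= 0 or self.half_time <= 0:
            raise ValueError("gamma and half_time must be > 0")
        if not 0 <= self.ash_primary <= self.ash_max:
            raise ValueError("ash_primary must lie in [0, ash_max]")

    @classmethod
    def from_dict(cls, d: dict) -> "BCPMParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known - {"version"}
        if unknown:
            raise ValueError(f"unknown BCPM constants: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def default(cls) -> "BCPMParams":
        """Load the packaged default parameter file."""
        ref = importlib.resources.files("bonepkpd.data") / "bcpm_default.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


#: per-site uniaxial stress magnitude (MPa) used when none is supplied;
#: chosen so the drug-free reference state is homeostatic at each site
DEFAULT_SITE_LOADS = {15.0: 1.0, 25.0: 2.0}


def site_load(f_bm0: float) -> float:
    return DEFAULT_SITE_LOADS.get(float(f_bm0), 1.0 + (f_bm0 - 15.0) / 10.0)


# ---------------------------------------------------------------------------
# Disease induction and specific surface

def rankl_pmo(t: float, params: BCPMParams) -> float:
    """Disease-related extra RANKL production rate (pM/day) at time t.

    Sigmoidal rise from 0 at onset to ``P_RANKL_max``, reaching half
    maximum ``half_time`` days after onset, with steepness ``gamma``.
    """
    if params.gamma <= 0 or params.half_time <= 0:
        raise ValueError("gamma and half_time must be > 0")
    dt = np.asarray(t, dtype=float) - params.t_onset
    dt = np.where(dt > 0, dt, 0.0)
    out = params.P_RANKL_max * dt ** params.gamma / (
        dt ** params.gamma + params.half_time ** params.gamma)
    return float(out) if out.ndim == 0 else out


_SV_COEF = np.array([32.3, -93.9, 134.0, -101.0, 28.8])


def specific_surface(f_vas):
    """Bone matrix–marrow interface area per total volume, mm²/mm³.

    Quintic correlation in the vascular porosity ``f_vas = 1 - f_bm/100``.
    Note the printed coefficients give 0.2 (not exactly 0) at ``f_vas = 1``;
    they are retained as published.
    """
    f = np.asarray(f_vas, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f_vas must lie in [0, 1]")
    powers = np.arange(1, 6)
    out = (_SV_COEF * f[..., None] ** powers).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Mineralization histogram

@dataclass
class MineralHistogram:
    """Tissue-age distribution of matrix, tracked as (mass, ash) cohorts.

    ``mass`` is in f_bm units (% of RVE volume) so the masses always sum to
    the matrix fraction.  New osteoid is appended as the youngest cohort at
    the primary ash fraction; every cohort relaxes exponentially toward the
    maximum ash fraction; resorption removes mass proportionally across
    cohorts (average-composition resorption).  The two oldest cohorts are
    merged (mass-weighted) when the cohort count exceeds ``max_bins`` —
    their ash fractions have converged, so the merge error is negligible.
    """

    mass: np.ndarray
    ash: np.ndarray
    max_bins: int = 200

    @classmethod
    def from_turnover(cls, f_bm: float, lam: float, params: BCPMParams,
                      n_bins: int = 150) -> "MineralHistogram":
        """Equilibrium histogram for relative turnover rate ``lam`` (1/day).

        Tissue age is exponentially distributed with rate ``lam``; ash
        follows the secondary-mineralization law at each age.
        """
        if lam <= 0:
            # no turnover: fully mineralized block
            return cls(np.array([f_bm]), np.array([params.ash_max]),
                       params.max_bins)
        edges = -np.log(np.linspace(1.0, 1e-6, n_bins + 1)) / lam
        w = np.exp(-lam * edges[:-1]) - np.exp(-lam * edges[1:])
        w = w / w.sum() * f_bm
        mid = 0.5 * (edges[:-1] + edges[1:])
        ash = params.ash_max - (params.ash_max - params.ash_primary) * np.exp(
            -params.kappa_mineral * mid)
        # youngest first
        return cls(mass=w.copy(), ash=ash.copy(), max_bins=params.max_bins)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @property
    def mean_ash(self) -> float:
        m = self.mass.sum()
        if m <= 0:
            return float(self.ash[-1]) if len(self.ash) else 0.0
        return float((self.mass * self.ash).sum() / m)

    def update(self, dt: float, formed: float, resorbed: float,
               params: BCPMParams) -> None:
        """Advance by ``dt`` days with the given formed/resorbed matrix
        amounts (f_bm units, >= 0)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.ash = params.ash_max - (params.ash_max - self.ash) * np.exp(
            -params.kappa_mineral * dt)
        total = self.mass.sum()
        if resorbed > 0 and total > 0:
            self.mass = self.mass * max(0.0, 1.0 - resorbed / total)
        if formed > 0:
            self.mass = np.concatenate([[formed], self.mass])
            self.ash = np.concatenate([[params.ash_primary], self.ash])
        while len(self.mass) > self.max_bins:
            m = self.mass[-2] + self.mass[-1]
            a = (self.mass[-2] * self.ash[-2] + self.mass[-1] * self.ash[-1]) \
                / m if m > 0 else self.ash[-1]
            self.mass = np.concatenate([self.mass[:-2], [m]])
            self.ash = np.concatenate([self.ash[:-2], [a]])

    def copy(self) -> "MineralHistogram":
        return MineralHistogram(self.mass.copy(), self.ash.copy(),
                                self.max_bins)


def apparent_density(f_bm: float, mean_ash: float,
                     params: BCPMParams) -> float:
    """Apparent density (g/cm³): matrix volume fraction times the tissue
    density, which is affine and increasing in the ash fraction."""
    rho_t = params.rho_tissue_a + params.rho_tissue_b * mean_ash
    if rho_t <= 0:
        raise ValueError("non-physical tissue density")
    return (f_bm / 100.0) * rho_t


def update_mineralization(state: "BoneState", dt: float,
                          params: BCPMParams, k_form: float,
                          kres_eff: float | None = None) -> "BoneState":
    """Advance the ash histogram of ``state`` by ``dt`` days using the
    current cell concentrations; returns a new state with f_bm and osteocyte
    count updated consistently with the histogram mass."""
    kres = params.k_res_nom if kres_eff is None else kres_eff
    formed = k_form * state.Oba * dt
    resorbed = kres * state.Oca * dt
    hist = state.histogram.copy()
    hist.update(dt, formed, resorbed, params)
    new_fbm = hist.total_mass
    return replace(state, f_bm=new_fbm,
                   Ot=state.Ot + params.eta * (new_fbm - state.f_bm),
                   histogram=hist)


# ---------------------------------------------------------------------------
# Mechanics

def stiffness_MPa(f_bm: float, mean_ash: float, params: BCPMParams) -> float:
    """Power-law stiffness in matrix volume fraction and ash fraction."""
    E = params.E0_MPa * (f_bm / 100.0) ** params.stiff_exp_fbm \
        * mean_ash ** params.stiff_exp_ash
    if E <= 0:
        raise ValueError("non-physical stiffness")
    return E


def strain_energy_density(load_MPa: float, f_bm: float, mean_ash: float,
                          params: BCPMParams) -> float:
    if load_MPa < 0:
        raise ValueError("load must be >= 0")
    return load_MPa ** 2 / (2.0 * stiffness_MPa(f_bm, mean_ash, params))


def mechanical_stimulus(load_MPa: float, f_bm: float, mean_ash: float,
                        params: BCPMParams, psi_ref: float) -> dict:
    """Multiplicative feedback factors from the strain-energy setpoint.

    Returns ``catabolic`` (applied to RANKL and sclerostin production;
    maximal, bounded by 2, at zero load) and ``anabolic`` (= 2 - catabolic,
    monotone increasing in load).  Both equal 1 at the homeostatic setpoint
    ``psi = psi_ref``.
    """
    psi = strain_energy_density(load_MPa, f_bm, mean_ash, params)
    u = (psi / psi_ref) ** params.mech_hill_n
    catabolic = 2.0 / (1.0 + u)
    return {"psi": psi, "catabolic": catabolic, "anabolic": 2.0 - catabolic}


# ---------------------------------------------------------------------------
# Signaling (quasi-steady-state algebra)

@dataclass
class SignalingState:
    """Algebraic signaling concentrations and the gating fractions they
    induce; all non-negative, all π values in [0, 1]."""

    tgf: float
    rankl: float
    rank: float
    opg: float
    pth: float
    sclerostin: float
    wnt: float
    mech_catabolic: float
    pi_act_obu_tgf: float
    pi_rep_obp_tgf: float
    pi_act_ocp_tgf: float
    pi_act_ocu_rl: float
    pi_act_ocp_rl: float
    pi_act_obp_wnt: float


def compute_signaling(Obp: float, Oba: float, Ocp: float, Oca: float,
                      t: float, params: BCPMParams, kres_eff: float,
                      mech_catabolic: float = 1.0,
                      pmo: bool = True) -> SignalingState:
    """Quasi-steady-state ligand concentrations and Hill gates.

    TGF-β is proportional to the matrix resorption rate; RANKL balances
    production on pre-osteoblasts (plus the disease term and the mechanical
    disuse factor) against turnover and competitive capture by OPG (from
    active osteoblasts, PTH-repressed) and RANK (on pre-osteoclasts);
    sclerostin from the osteocyte network is disuse-promoted and gates Wnt.
    """
    g = mech_catabolic
    tgf = params.tgf_basal + params.tgf_per_resorption * kres_eff * Oca
    opg = params.opg_per_oba * Oba * hill_repressor(params.pth0,
                                                    params.K_pth_opg)
    rank = params.rank_per_ocp * Ocp
    production = params.prl_per_obp * Obp * g
    if pmo:
        production = production + rankl_pmo(t, params)
    rankl = production / (params.d_rankl *
                          (1.0 + opg / params.K_opg + rank / params.K_rank))
    scl = params.scl0 * g ** params.scl_mech_exp
    wnt = params.wnt0 / (1.0 + scl / params.K_scl)
    return SignalingState(
        tgf=tgf, rankl=rankl, rank=rank, opg=opg, pth=params.pth0,
        sclerostin=scl, wnt=wnt, mech_catabolic=g,
        pi_act_obu_tgf=hill_activator(tgf, params.K_tgf_obu),
        pi_rep_obp_tgf=hill_repressor(tgf, params.K_tgf_obp),
        pi_act_ocp_tgf=hill_activator(tgf, params.K_tgf_ocp),
        pi_act_ocu_rl=hill_activator(rankl, params.K_rl_ocu),
        pi_act_ocp_rl=hill_activator(rankl, params.K_rl_ocp),
        pi_act_obp_wnt=hill_activator(wnt, params.K_wnt),
    )


# ---------------------------------------------------------------------------
# State and right-hand side

@dataclass
class BoneState:
    """Cell concentrations (pM), matrix fraction (%), ash histogram and the
    optional microdamage variable."""

    Obp: float
    Oba: float
    Ocp: float
    Oca: float
    Ot: float
    f_bm: float
    histogram: MineralHistogram
    damage: float = 0.0

    def cells(self) -> np.ndarray:
        return np.array([self.Obp, self.Oba, self.Ocp, self.Oca])

    def as_vector(self) -> np.ndarray:
        """ODE state: [Obp, Oba, Ocp, Oca, Ot, f_bm, damage]."""
        return np.array([self.Obp, self.Oba, self.Ocp, self.Oca,
                         self.Ot, self.f_bm, self.damage])


N_BONE = 7  # length of the BoneState ODE vector


def cell_rhs(y: np.ndarray, t: float, params: BCPMParams, k_form: float,
             kres_eff: float, apoptosis_eff: float,
             mech_catabolic: float = 1.0, pmo: bool = True,
             psi: float = 0.0) -> np.ndarray:
    """Derivatives of [Obp, Oba, Ocp, Oca, Ot, f_bm, damage].

    ``kres_eff`` and ``apoptosis_eff`` are supplied by the drug-coupling
    layer; nominal values reproduce the drug-free model.
    """
    Obp, Oba, Ocp, Oca = y[0], y[1], y[2], y[3]
    sig = compute_signaling(Obp, Oba, Ocp, Oca, t, params, kres_eff,
                            mech_catabolic, pmo)
    dObp = (params.D_Obu * params.Obu_pool * sig.pi_act_obu_tgf
            - params.D_Obp * Obp * sig.pi_rep_obp_tgf
            + params.P_Obp * Obp * sig.pi_act_obp_wnt)
    dOba = params.D_Obp * Obp * sig.pi_rep_obp_tgf - params.Delta_Oba * Oba
    dOcp = (params.D_Ocu * params.Ocu_pool * sig.pi_act_ocu_rl
            - params.D_Ocp * Ocp * sig.pi_act_ocp_rl)
    dOca = (params.D_Ocp * Ocp * sig.pi_act_ocp_rl
            - apoptosis_eff * Oca * sig.pi_act_ocp_tgf)
    dfbm = -kres_eff * Oca + k_form * Oba
    dOt = params.eta * dfbm
    if params.damage_on:
        ddam = params.dam_accum * psi - params.dam_repair * y[6] * Oca
    else:
        ddam = 0.0
    return np.array([dObp, dOba, dOcp, dOca, dOt, dfbm, ddam])


def bcpm_rhs(state: BoneState, t: float, params: BCPMParams, k_form: float,
             kres_eff: float | None = None,
             apoptosis_eff: float | None = None,
             mech_catabolic: float = 1.0, pmo: bool = True) -> np.ndarray:
    """Right-hand side evaluated on a :class:`BoneState` (validates input)."""
    if min(state.Obp, state.Oba, state.Ocp, state.Oca) < -1e-12:
        raise ValueError("negative cell concentrations")
    kres = params.k_res_nom if kres_eff is None else kres_eff
    apo = params.A_Oca_nom if apoptosis_eff is None else apoptosis_eff
    return cell_rhs(state.as_vector(), t, params, k_form, kres, apo,
                    mech_catabolic, pmo)


# ---------------------------------------------------------------------------
# Steady state and site initialization

def steady_state_cells(params: BCPMParams) -> np.ndarray:
    """Healthy steady state of [Obp, Oba, Ocp, Oca]: drug-free, disease off,
    mechanical factors at the homeostatic setpoint (= 1)."""
    if params.D_Obu * params.Obu_pool == 0 and \
            params.D_Ocu * params.Ocu_pool == 0:
        return np.zeros(4)

    def res(x):
        y = np.concatenate([np.abs(x), [0.0, 0.0, 0.0]])
        return cell_rhs(y, 0.0, params, k_form=0.0,
                        kres_eff=params.k_res_nom,
                        apoptosis_eff=params.A_Oca_nom,
                        mech_catabolic=1.0, pmo=False)[:4]

    x0 = np.array([4e-3, 1.5e-3, 2.5e-3, 1.4e-3])
    sol = root(res, x0, method="hybr", tol=1e-14)
    cells = np.abs(sol.x)
    # judge convergence by the residual itself, relative to the entering
    # differentiation fluxes (hybr can report failure at an exact root)
    scale = max(params.D_Obu * params.Obu_pool,
                params.D_Ocu * params.Ocu_pool, 1e-12)
    if np.max(np.abs(res(cells))) > 1e-8 * scale:
        raise RuntimeError("no steady state found; parameterization is "
                           "inconsistent")
    return cells


@dataclass
class SiteContext:
    """Everything that pins the model to one bone site: baseline matrix
    fraction, load, the homeostatic strain-energy setpoint, and the
    formation rate that balances resorption at baseline."""

    f_bm0: float
    load_MPa: float
    psi_ref: float
    k_form: float
    state0: BoneState


def initialize_site(params: BCPMParams, f_bm0: float,
                    load_MPa: float | None = None) -> SiteContext:
    """Build the homeostatic baseline state at a site.

    The ash histogram is initialized at its turnover equilibrium, the
    strain-energy setpoint is evaluated at the baseline state (so the
    mechanical factors are exactly 1 there), and — if ``k_form`` is not set —
    formation is balanced against resorption so the baseline is a true
    fixed point.
    """
    if not 0 < f_bm0 < 100:
        raise ValueError("f_bm0 must be in (0, 100)")
    if load_MPa is None:
        load_MPa = site_load(f_bm0)
    cells = steady_state_cells(params)
    Obp, Oba, Ocp, Oca = cells
    if params.k_form is not None:
        k_form = params.k_form
    elif Oba > 0:
        k_form = params.k_res_nom * Oca / Oba
    else:
        k_form = 0.0
    lam = params.k_res_nom * Oca / f_bm0 if f_bm0 > 0 else 0.0
    hist = MineralHistogram.from_turnover(f_bm0, lam, params)
    ash = hist.mean_ash
    psi_ref = strain_energy_density(load_MPa, f_bm0, ash, params)
    state0 = BoneState(Obp=Obp, Oba=Oba, Ocp=Ocp, Oca=Oca,
                       Ot=params.eta * f_bm0, f_bm=f_bm0, histogram=hist)
    return SiteContext(f_bm0=f_bm0, load_MPa=load_MPa, psi_ref=psi_ref,
                       k_form=k_form, state0=state0)


def steady_state(params: BCPMParams, f_bm0: float = 15.0,
                 load_MPa: float | None = None) -> BoneState:
    """Homeostatic :class:`BoneState` used as the t = 0 condition."""
    return initialize_site(params, f_bm0, load_MPa).state0


# ---------------------------------------------------------------------------
# Drug-free simulation (used for the pre-treatment disease phase)

@dataclass
class BCPMTimeSeries:
    t: np.ndarray
    cells: np.ndarray        # columns Obp, Oba, Ocp, Oca
    ot: np.ndarray
    f_bm: np.ndarray
    mean_ash: np.ndarray
    rho: np.ndarray
    damage: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_d": self.t, "obp": self.cells[:, 0],
            "oba": self.cells[:, 1], "ocp": self.cells[:, 2],
            "oca": self.cells[:, 3], "ot": self.ot,
            "f_bm_pct": self.f_bm, "ash_mean": self.mean_ash,
            "rho_g_cm3": self.rho,
        })


def simulate_bcpm(params: BCPMParams, site: SiteContext, days: float,
                  pmo: bool = True, t0: float = 0.0,
                  state: BoneState | None = None,
                  chunk_days: float = 30.0, mineral_dt: float = 1.0,
                  rtol: float = 1e-8,
                  atol: float = 1e-12) -> tuple[BCPMTimeSeries, BoneState]:
    """Integrate the drug-free model for ``days``, starting from ``state``
    (default: the site baseline).

    Cells and f_bm are integrated with an adaptive stiff solver in chunks;
    within each chunk the mechanics sees a frozen mean ash fraction, and the
    ash histogram is advanced in ``mineral_dt`` substeps from the dense
    solver output.  Returns the sampled series and the final state.
    """
    if state is None:
        state = site.state0
    hist = state.histogram.copy()
    y = state.as_vector()
    ts, ys, ashes = [t0], [y.copy()], [hist.mean_ash]

    t = t0
    t_end = t0 + days
    while t < t_end - 1e-9:
        t1 = min(t + chunk_days, t_end)
        ash = hist.mean_ash
        mech = mechanical_stimulus(site.load_MPa, max(y[5], 1e-6), ash,
                                   params, site.psi_ref)["catabolic"]

        sol = solve_ivp(
            lambda tt, yy: cell_rhs(yy, tt, params, site.k_form,
                                    params.k_res_nom, params.A_Oca_nom,
                                    mech, pmo),
            (t, t1), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True)
        if not sol.success:
            raise RuntimeError(f"BCPM solver failed at t={t}: {sol.message}")
        sub = np.arange(t, t1, mineral_dt)[1:]
        sub = np.append(sub, t1)
        prev_t, prev_y = t, y
        for tt in sub:
            yy = sol.sol(tt)
            dt = tt - prev_t
            formed = site.k_form * 0.5 * (prev_y[1] + yy[1]) * dt
            resorbed = params.k_res_nom * 0.5 * (prev_y[3] + yy[3]) * dt
            hist.update(dt, formed, resorbed, params)
            prev_t, prev_y = tt, yy
        y = sol.y[:, -1]
        # keep f_bm identical to the histogram bookkeeping; osteocytes
        # follow so the Ot - eta*f_bm first integral is preserved exactly
        y[4] += params.eta * (hist.total_mass - y[5])
        y[5] = hist.total_mass
        t = t1
        ts.append(t)
        ys.append(y.copy())
        ashes.append(hist.mean_ash)

    ts = np.array(ts)
    ys = np.array(ys)
    ashes = np.array(ashes)
    rho = np.array([apparent_density(fb, a, params)
                    for fb, a in zip(ys[:, 5], ashes)])
    series = BCPMTimeSeries(t=ts, cells=ys[:, :4], ot=ys[:, 4],
                            f_bm=ys[:, 5], mean_ash=ashes, rho=rho,
                            damage=ys[:, 6])
    final = BoneState(Obp=y[0], Oba=y[1], Ocp=y[2], Oca=y[3], Ot=y[4],
                      f_bm=y[5], histogram=hist, damage=y[6])
    return series, final


# ---------------------------------------------------------------------------
# Bone density gain

def bdg(rho: np.ndarray, t: np.ndarray, t0: float) -> np.ndarray:
    """Percent change of apparent density relative to its value at ``t0``
    (treatment start)."""
    t = np.asarray(t, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if t0 < t[0] - 1e-9 or t0 > t[-1] + 1e-9:
        raise ValueError("t0 outside the series")
    rho0 = float(np.interp(t0, t, rho))
    if rho0 <= 0:
        raise ValueError("reference density must be > 0")
    return (rho - rho0) / rho0 * 100.0


__all__ = [
    "hill_activator", "hill_repressor", "BCPMParams", "DEFAULT_SITE_LOADS",
    "site_load", "rankl_pmo", "specific_surface", "MineralHistogram",
    "apparent_density", "update_mineralization", "stiffness_MPa",
    "strain_energy_density", "mechanical_stimulus", "SignalingState",
    "compute_signaling", "BoneState", "cell_rhs", "bcpm_rhs",
    "steady_state_cells", "SiteContext", "initialize_site", "steady_state",
    "BCPMTimeSeries", "simulate_bcpm", "bdg",
]
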