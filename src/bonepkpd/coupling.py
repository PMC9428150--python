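"""Coupling of the alendronate PK model to the bone cell population model.

The bone compartment (BC) of the 3-compartment "in parallel" PK model is
split into an *active* sub-compartment — drug deposited near the bone
matrix–marrow interface, accessible to resorbing osteoclasts — and an
*inactive* one (drug buried in the matrix).  The split is algebraic in the
bone matrix fraction through the specific-surface correlation, the active
concentration can saturate, and the drug released by resorption returns to
plasma at the osteoclast-controlled rate k_el,BC = k_res·Oc_a.

Released active drug lowers the resorbing capacity k_res (closed-form fixed
point of the implicit self-inhibition) and raises osteoclast apoptosis.
Six coupling variants switch these mechanisms on and off.

Unit bridge
-----------
Concentrations are amount / V_Bone in mM.  The drug-effect constants
``pi_act``/``pi_rep`` enter only through the products
``pi · k_res·Oc_a · [Ale]``; the cell-concentration units of the source
model family are not fully determined, so the products carry an explicit
dimensionless ``effect_scale`` (default calibrated once with the default
BCPM parameter file, documented in the methods note).  Setting
``effect_scale = 1`` recovers the raw printed units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import bcpm as _bcpm
from .bcpm import (BCPMParams, BoneState, MineralHistogram, SiteContext,
                   apparent_density, bdg, cell_rhs, initialize_site,
                   mechanical_stimulus, simulate_bcpm, specific_surface)
from .pk import (BC, CC, GUT, IC, NCT, URINE, N_COMP, DoseSchedule, PKParams,
                 build_schedule)


def skeleton_average_fbm(fbm_cortical: float = 93.0,
                         vol_frac_cortical: float = 0.8,
                         fbm_trabecular: float = 14.0,
                         vol_frac_trabecular: float = 0.2) -> float:
    """Skeleton-average bone matrix fraction (%), the harmonic mean of the
    cortical and trabecular matrix fractions weighted by their shares of
    total bone-tissue volume (defaults: 93% / 14% with an 80/20 split,
    giving 43.7%)."""
    if not np.isclose(vol_frac_cortical + vol_frac_trabecular, 1.0):
        raise ValueError("tissue-volume fractions must sum to 1")
    return 1.0 / (vol_frac_cortical / fbm_cortical
                  + vol_frac_trabecular / fbm_trabecular)


@dataclass
class PDParams:
    """Drug-effect and bone-geometry constants of the coupled model."""

    pi_act: float = 12.98      # day/mM, apoptosis upregulation
    pi_rep: float = 14.31      # day/mM, resorbing-capacity downregulation
    f_sat: float | None = 7.72e-2  # mM, saturation constant of the active BC
    f_bm0: float = 5.0         # %, below this all tissue is superficial
    V_bone_m3: float = 2.23e-3  # total skeletal bone-tissue volume
    molar_mass: float = 249.1  # g/mol
    f_bm_aver: float | None = None  # % skeleton average; None -> computed
    effect_scale: float = 1.25e3  # unit bridge for the pi products (see above)

    def __post_init__(self) -> None:
        if not 0 < self.f_bm0 < 100:
            raise ValueError("f_bm0 must be in (0, 100)")
        if self.V_bone_m3 <= 0 or self.molar_mass <= 0:
            raise ValueError("V_bone_m3 and molar_mass must be > 0")
        if self.pi_act < 0 or self.pi_rep < 0:
            raise ValueError("pi constants must be >= 0")
        if self.f_sat is not None and self.f_sat <= 0:
            raise ValueError("f_sat must be > 0 (or None)")
        if self.f_bm_aver is None:
            self.f_bm_aver = skeleton_average_fbm()

    @property
    def V_bone_L(self) -> float:
        return self.V_bone_m3 * 1e3

    @property
    def sv0(self) -> float:
        """Specific surface at the reference matrix fraction f_bm0."""
        return specific_surface(1.0 - self.f_bm0 / 100.0)

    def conc_mM(self, amount_mg: float) -> float:
        """Concentration over the total bone-tissue volume (Eq-16 style)."""
        return amount_mg / self.molar_mass / self.V_bone_L

    def amount_mg(self, conc_mM: float) -> float:
        return conc_mM * self.molar_mass * self.V_bone_L


@dataclass(frozen=True)
class VariantSpec:
    """Flags encoding the six coupling scenarios."""

    id: str
    affects_kres: bool
    affects_apoptosis: bool
    active_split: bool
    saturation: bool

    _TABLE = {
        "pkpd1": (True, True, True, True),
        "pkpd2": (True, False, True, True),
        "pkpd3": (False, True, True, True),
        "pkpd4": (True, True, True, False),
        "pkpd5": (True, True, False, False),
        "pkpd6": (True, True, False, True),
    }

    @classmethod
    def from_id(cls, variant_id: str) -> "VariantSpec":
        vid = variant_id.lower().replace("-", "")
        if vid not in cls._TABLE:
            raise ValueError(f"unknown variant {variant_id!r}")
        return cls(vid, *cls._TABLE[vid])


def active_surface_factor(f_bm: float, pd: PDParams):
    """Fraction g of the bone-compartment drug that sits on the active
    (resorbable) surface; 1 below f_bm0 (all tissue superficial), 0 at
    f_bm = 100 (no free surface), clamped to [0, 1]."""
    f = np.asarray(f_bm, dtype=float)
    if np.any(f < 0) or np.any(f > 100):
        raise ValueError("f_bm must lie in [0, 100]")
    sv = specific_surface(1.0 - f / 100.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(f <= pd.f_bm0, 1.0,
                     sv / np.maximum(f, 1e-12) * pd.f_bm0 / pd.sv0)
    g = np.clip(g, 0.0, 1.0)
    return float(g) if g.ndim == 0 else g


def active_amount(ale_bc_mg: float, f_bm: float, pd: PDParams,
                  saturation: bool = True) -> float:
    """Amount of drug (mg) in the active sub-compartment.

    Unsaturated split: g·Ale_BC.  With saturation, the active concentration
    is capped at f_sat·g; beyond the cap any further inflow accrues to the
    inactive part only (the split is algebraic, so the cap re-routes it).
    """
    if ale_bc_mg < 0:
        raise ValueError("Ale_BC must be >= 0")
    g = active_surface_factor(f_bm, pd)
    act = g * ale_bc_mg
    if saturation and pd.f_sat is not None:
        act = min(act, pd.amount_mg(pd.f_sat * g))
    return act


def kel_bc(kres_eff: float, oca: float) -> float:
    """Osteoclast-mediated drug release rate from bone, k_el,BC (1/day)."""
    if kres_eff < 0 or oca < 0:
        raise ValueError("inputs must be >= 0")
    return kres_eff * oca


def effective_kres(oca: float, ale_act_mM: float, pd: PDParams,
                   k_res_nom: float) -> float:
    """Drug-reduced resorbing capacity (closed form).

    Fixed point of the implicit self-inhibition in which the inhibiting
    concentration is the drug released by resorption itself:
    k_res = k_res,nom / (1 + Π_rep·k_res,nom·Oc_a·[Ale_act]).
    """
    denom = 1.0 + pd.pi_rep * pd.effect_scale * k_res_nom * oca * ale_act_mM
    return k_res_nom / denom


def effective_apoptosis(oca: float, ale_act_mM: float, kres_eff: float,
                        pd: PDParams, a_nom: float) -> float:
    """Drug-increased osteoclast apoptosis rate,
    A = A_nom·(1 + Π_act·k_res·Oc_a·[Ale_act]) with the effective k_res."""
    return a_nom * (1.0 + pd.pi_act * pd.effect_scale * kres_eff * oca
                    * ale_act_mM)


# ---------------------------------------------------------------------------
# Coupled right-hand side

N_STATE = N_COMP + _bcpm.N_BONE  # 6 PK + 7 bone


def _drug_effects(ale_bc_mg: float, f_bm: float, oca: float,
                  bcpm: BCPMParams, pd: PDParams, variant: VariantSpec
                  ) -> tuple[float, float, float, float]:
    """(kres_eff, apoptosis_eff, release_amount_mg, inflow_gate)."""
    if variant.active_split:
        ale_rel = active_amount(ale_bc_mg, f_bm, pd, variant.saturation)
        gate = 1.0
    else:
        ale_rel = ale_bc_mg
        gate = 1.0
        if variant.saturation and pd.f_sat is not None:
            # total-BC cap: block CC->BC inflow as the cap is approached
            c = pd.conc_mM(ale_bc_mg)
            gate = float(np.clip((pd.f_sat - c) / (0.02 * pd.f_sat), 0.0, 1.0))
    c_eff = pd.conc_mM(ale_rel)
    kres = effective_kres(oca, c_eff, pd, bcpm.k_res_nom) \
        if variant.affects_kres else bcpm.k_res_nom
    apo = effective_apoptosis(oca, c_eff, kres, pd, bcpm.A_Oca_nom) \
        if variant.affects_apoptosis else bcpm.A_Oca_nom
    return kres, apo, ale_rel, gate


def coupled_rhs(y: np.ndarray, t: float, pk: PKParams, bcpm: BCPMParams,
                pd: PDParams, variant: VariantSpec, site: SiteContext,
                mean_ash: float, infusion_rate: float = 0.0,
                pmo: bool = True) -> np.ndarray:
    """Derivative of the joint state [PK amounts (6) | bone state (7)].

    The BC→CC return flux is k_el,BC·[Ale_act]·V_Bone/(f_bm_aver/100): the
    local per-volume release scaled to the whole skeleton through the
    average matrix fraction.  Time ``t`` is measured from disease onset.
    """
    y = np.asarray(y, dtype=float)
    pkv = y[:N_COMP]
    bone = y[N_COMP:]
    f_bm = max(bone[5], 1e-6)
    oca = max(bone[3], 0.0)
    ale_bc = max(pkv[BC], 0.0)

    kres_eff, apo_eff, ale_rel, gate = _drug_effects(
        ale_bc, f_bm, oca, bcpm, pd, variant)
    k_release = kel_bc(kres_eff, oca)
    # mg/day: k_el,BC · [Ale_act] · V_Bone / (f_bm_aver/100)
    flux_back = k_release * ale_rel / (pd.f_bm_aver / 100.0)

    dpk = np.zeros(N_COMP)
    absorbed = pk.F * pk.k_CC * pkv[GUT]
    dpk[GUT] = -pk.k_CC * pkv[GUT]
    dpk[CC] = (absorbed + infusion_rate + flux_back
               + pk.k_el_NCT * pkv[NCT]
               - (pk.k_BC * gate + pk.k_NCT + pk.k_el_urine) * pkv[CC])
    dpk[NCT] = pk.k_NCT * pkv[CC] - pk.k_el_NCT * pkv[NCT]
    dpk[BC] = pk.k_BC * gate * pkv[CC] - flux_back
    dpk[URINE] = pk.k_el_urine * pkv[CC]

    mech = mechanical_stimulus(site.load_MPa, f_bm, mean_ash, bcpm,
                               site.psi_ref)
    dbone = cell_rhs(bone, t, bcpm, site.k_form, kres_eff, apo_eff,
                     mech["catabolic"], pmo, psi=mech["psi"])
    return np.concatenate([dpk, dbone])


# ---------------------------------------------------------------------------
# Treatment simulation

@dataclass
class CoupledTimeSeries:
    """Daily-sampled joint trajectory of a treatment simulation.

    Times are days since disease onset; ``treatment_start`` marks the first
    dose.  ``bdg_pct`` is referenced to the apparent density at treatment
    start and is NaN before it.
    """

    t: np.ndarray
    pk_amounts: np.ndarray   # columns: gut, cc, nct, bc, ic, urine (mg)
    cells: np.ndarray        # columns: obp, oba, ocp, oca (pM)
    ot: np.ndarray
    f_bm: np.ndarray
    mean_ash: np.ndarray
    rho: np.ndarray
    bdg_pct: np.ndarray
    treatment_start: float
    params_pk: PKParams
    site: SiteContext

    @property
    def serum_ng_per_mL(self) -> np.ndarray:
        return self.pk_amounts[:, CC] / self.params_pk.V_c * 1e3

    @property
    def cumulative_urine_mg(self) -> np.ndarray:
        return self.pk_amounts[:, URINE]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({
            "time_d": self.t,
            "gut_mg": self.pk_amounts[:, GUT],
            "cc_mg": self.pk_amounts[:, CC],
            "nct_mg": self.pk_amounts[:, NCT],
            "bc_mg": self.pk_amounts[:, BC],
            "ic_mg": self.pk_amounts[:, IC],
            "urine_mg": self.pk_amounts[:, URINE],
            "serum_ng_ml": self.serum_ng_per_mL,
            "obp": self.cells[:, 0], "oba": self.cells[:, 1],
            "ocp": self.cells[:, 2], "oca": self.cells[:, 3],
            "ot": self.ot, "f_bm_pct": self.f_bm,
            "ash_mean": self.mean_ash, "rho_g_cm3": self.rho,
            "bdg_pct": self.bdg_pct,
        })
        return df


def simulate_treatment(site_f_bm: float, regimen: str | DoseSchedule,
                       variant: VariantSpec | str, pk: PKParams,
                       bcpm_params: BCPMParams, pd: PDParams,
                       years_pre: float = 19.0, years_treat: float = 2.0,
                       load_MPa: float | None = None,
                       rtol: float = 1e-7, atol: float = 1e-12,
                       pre_chunk_days: float = 30.0,
                       sample_dt: float = 1.0,
                       pre_cache: dict | None = None) -> CoupledTimeSeries:
    """Two-phase simulation: disease induction, then dosing.

    Phase 1 starts at the healthy steady state and runs the drug-free model
    with the osteoporotic RANKL induction for ``years_pre`` years.  Phase 2
    applies the dosing regimen (oral boluses as gut jumps with integration
    restarts, infusions as constant inputs) for ``years_treat`` years with
    the disease term still active.  The ash histogram advances in daily
    substeps from the dense solver output.
    """
    if isinstance(variant, str):
        variant = VariantSpec.from_id(variant)
    days_pre = years_pre * 365.0
    days_treat = years_treat * 365.0

    # the drug-free disease phase depends only on the site and BCPM
    # parameters; callers comparing variants or regimens can share it
    key = (site_f_bm, load_MPa, years_pre)
    if pre_cache is not None and key in pre_cache:
        site, pre, state = pre_cache[key]
    else:
        site = initialize_site(bcpm_params, site_f_bm, load_MPa)
        pre, state = simulate_bcpm(bcpm_params, site, days_pre, pmo=True,
                                   chunk_days=pre_chunk_days, rtol=1e-8)
        if pre_cache is not None:
            pre_cache[key] = (site, pre, state)

    if isinstance(regimen, DoseSchedule):
        schedule = regimen
    else:
        schedule = build_schedule(regimen, max(days_treat, 1.0))
    if schedule.last_time > days_treat:
        raise ValueError("regimen extends past the treatment horizon")

    t0 = days_pre
    hist = state.histogram.copy()
    y = np.concatenate([np.zeros(N_COMP), state.as_vector()])

    # interval boundaries: dose events (relative to t0) + chunking of gaps
    events = sorted({0.0, days_treat}
                    | {e.time for e in schedule.events}
                    | {e.time + e.duration for e in schedule.events
                       if e.duration > 0})
    boundaries = [0.0]
    max_gap = 30.0
    for a, b in zip(events[:-1], events[1:]):
        n = int(np.ceil((b - a) / max_gap))
        boundaries.extend(np.linspace(a, b, n + 1)[1:].tolist())
    bolus_at = {}
    for ev in schedule.events:
        if ev.route == "oral":
            bolus_at[ev.time] = bolus_at.get(ev.time, 0.0) + ev.amount

    def infusion(a, b):
        tm = 0.5 * (a + b)
        return sum(ev.amount / ev.duration for ev in schedule.events
                   if ev.route == "iv" and ev.duration > 0
                   and ev.time <= tm < ev.time + ev.duration)

    ts = [t0]
    rows = [y.copy()]
    ashes = [hist.mean_ash]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if a in bolus_at:
            y[GUT] += bolus_at[a]
        rate = infusion(a, b)
        sol = solve_ivp(
            lambda tt, yy: coupled_rhs(yy, tt, pk, bcpm_params, pd, variant,
                                       site, hist.mean_ash, rate, pmo=True),
            (t0 + a, t0 + b), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True)
        if not sol.success:
            raise RuntimeError(f"coupled solver failed at day {a}: "
                               f"{sol.message}")
        sub = np.arange(t0 + a, t0 + b, sample_dt)[1:]
        sub = np.append(sub, t0 + b)
        prev_t, prev_y = t0 + a, y
        for tt in sub:
            yy = sol.sol(tt)
            dt = tt - prev_t
            fb = max(yy[N_COMP + 5], 1e-6)
            kres_eff, _, _, _ = _drug_effects(max(yy[BC], 0.0), fb,
                                              max(yy[N_COMP + 3], 0.0),
                                              bcpm_params, pd, variant)
            formed = site.k_form * 0.5 * (prev_y[N_COMP + 1]
                                          + yy[N_COMP + 1]) * dt
            resorbed = kres_eff * 0.5 * (prev_y[N_COMP + 3]
                                         + yy[N_COMP + 3]) * dt
            hist.update(dt, formed, resorbed, bcpm_params)
            prev_t, prev_y = tt, yy
            ts.append(tt)
            rows.append(yy.copy())
            ashes.append(hist.mean_ash)
        y = sol.y[:, -1]
        # f_bm follows the histogram; osteocytes follow f_bm so the
        # Ot - eta*f_bm first integral is preserved exactly
        y[N_COMP + 4] += bcpm_params.eta * (hist.total_mass - y[N_COMP + 5])
        y[N_COMP + 5] = hist.total_mass

    # stitch phase 1 (drug-free) and phase 2
    n_pre = len(pre.t)
    t_all = np.concatenate([pre.t[:-1], np.array(ts)])
    pk_all = np.vstack([np.zeros((n_pre - 1, N_COMP)),
                        np.array(rows)[:, :N_COMP]])
    bone_all = np.vstack([
        np.column_stack([pre.cells, pre.ot, pre.f_bm, pre.damage])[:-1],
        np.array(rows)[:, N_COMP:]])
    ash_all = np.concatenate([pre.mean_ash[:-1], np.array(ashes)])
    rho_all = np.array([apparent_density(fb, a, bcpm_params)
                        for fb, a in zip(bone_all[:, 5], ash_all)])
    bdg_all = np.full_like(rho_all, np.nan)
    mask = t_all >= t0 - 1e-9
    bdg_all[mask] = bdg(rho_all[mask], t_all[mask], t0)

    return CoupledTimeSeries(
        t=t_all, pk_amounts=pk_all, cells=bone_all[:, :4], ot=bone_all[:, 4],
        f_bm=bone_all[:, 5], mean_ash=ash_all, rho=rho_all, bdg_pct=bdg_all,
        treatment_start=t0, params_pk=pk, site=site)


__all__ = [
    "skeleton_average_fbm", "PDParams", "VariantSpec",
    "active_surface_factor", "active_amount", "kel_bc", "effective_kres",
    "effective_apoptosis", "coupled_rhs", "CoupledTimeSeries",
    "simulate_treatment", "N_STATE",
]
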