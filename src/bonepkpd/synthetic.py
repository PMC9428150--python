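"""Synthetic clinical-style curves for closed-loop testing.

The clinical curves the coupled model is meant to fit (single-dose serum,
short- and long-term cumulative urine, and 2-year bone density gain at two
sites) are not deposited with the original studies, so all fitting and
sensitivity machinery is exercised against synthetic curves generated from
known parameter sets.  Sampling grids mimic the designs of the cited
studies; noise is multiplicative lognormal (mean-preserving) and fully
seeded, so a fixed seed reproduces files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bcpm import BCPMParams
from .calibration import (KIND_REGIMEN, KIND_UNIT, ClinicalDataset,
                          PKPDForward, pk_curve)
from .coupling import PDParams, VariantSpec
from .pk import PKParams, Topology
from .reference import PK_TOPOLOGY_FITS, PKPD_VARIANT_FITS


def _default_grids() -> dict[str, np.ndarray]:
    return {
        # dense sampling over the first two days (single 70 mg oral dose)
        "serum": np.array([0.02, 0.04, 0.06, 0.08, 0.125, 0.167, 0.25,
                           0.333, 0.5, 0.75, 1.0, 1.5, 2.0]),
        "short_urine": np.array([0.125, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]),
        # cumulative urine over ~18 months after the 4-day IV protocol
        "long_urine": np.array([1.0, 2.0, 4.0, 7.0, 14.0, 30.0, 60.0, 90.0,
                                135.0, 180.0, 270.0, 360.0, 450.0, 540.0]),
        # monthly bone density gain over the 2-year weekly treatment
        "bdg": np.arange(30.0, 731.0, 30.0),
    }


@dataclass
class SyntheticSpec:
    """True parameter set, sampling grids and noise model.

    ``model`` selects the generating forward model: ``"pk"`` produces the
    three PK curves from a PK-only topology (the natural truth for PK
    parameter-recovery experiments); ``"pkpd"`` produces all four curve
    kinds, BDG at both sites, from the coupled model (default truth: the
    fitted coupled-model constants plus the default BCPM parameter file).
    """

    model: str = "pkpd"
    topology: Topology = Topology.THREE_C_PARALLEL
    pk: PKParams | None = None
    pd_params: PDParams | None = None
    bcpm: BCPMParams | None = None
    variant: str = "pkpd1"
    sites: tuple[float, float] = (15.0, 25.0)
    years_pre: float = 19.0
    grids: dict = field(default_factory=_default_grids)
    sigma: dict = field(default_factory=dict)   # per-kind lognormal sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("pk", "pkpd"):
            raise ValueError("model must be 'pk' or 'pkpd'")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("noise sigma must be >= 0")
        for g in self.grids.values():
            if np.any(np.diff(np.asarray(g, dtype=float)) <= 0):
                raise ValueError("grids must be strictly increasing")
        if self.pk is None:
            if self.model == "pk":
                self.pk = PKParams(**PK_TOPOLOGY_FITS[self.topology])
            else:
                self.pk = PKParams(**PKPD_VARIANT_FITS[self.variant]["pk"],
                                   k_el_BC=0.0)
        if self.model == "pkpd":
            if self.pd_params is None:
                v = PKPD_VARIANT_FITS[self.variant]
                self.pd_params = PDParams(pi_act=v["pi_act"],
                                          pi_rep=v["pi_rep"],
                                          f_sat=v["f_sat"])
            if self.bcpm is None:
                self.bcpm = BCPMParams.default()

    @classmethod
    def pk_only(cls, topology: Topology = Topology.THREE_C_PARALLEL,
                seed: int = 0, sigma: float = 0.0,
                pk: PKParams | None = None) -> "SyntheticSpec":
        kinds = ("serum", "short_urine", "long_urine")
        return cls(model="pk", topology=topology, pk=pk, seed=seed,
                   sigma={k: sigma for k in kinds})


def _apply_noise(values: np.ndarray, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return values
    # mean-preserving multiplicative lognormal noise
    return values * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=values.shape)


def generate_synthetic_clinical(spec: SyntheticSpec,
                                out_dir: str | Path | None = None
                                ) -> list[ClinicalDataset]:
    """Simulate the generating model on the spec's grids, add noise, and
    (optionally) write CSV + JSON-sidecar files."""
    rng = np.random.default_rng(spec.seed)
    datasets: list[ClinicalDataset] = []

    pk_kinds = ("serum", "short_urine", "long_urine")
    if spec.model == "pk":
        for kind in pk_kinds:
            t = np.asarray(spec.grids[kind], dtype=float)
            y = pk_curve(kind, spec.pk, spec.topology, t)
            y = _apply_noise(y, spec.sigma.get(kind, 0.0), rng)
            datasets.append(ClinicalDataset(
                name=kind, kind=kind, regimen=KIND_REGIMEN[kind], t=t,
                values=y, unit=KIND_UNIT[kind]))
    else:
        forward = PKPDForward(spec.variant, spec.bcpm,
                              years_pre=spec.years_pre, sites=spec.sites)
        for kind in pk_kinds:
            t = np.asarray(spec.grids[kind], dtype=float)
            y = forward.curve(kind, t, spec.sites[0], spec.pk,
                              spec.pd_params)
            y = _apply_noise(y, spec.sigma.get(kind, 0.0), rng)
            datasets.append(ClinicalDataset(
                name=kind, kind=kind, regimen=KIND_REGIMEN[kind], t=t,
                values=y, unit=KIND_UNIT[kind]))
        for site in spec.sites:
            t = np.asarray(spec.grids["bdg"], dtype=float)
            y = forward.curve("bdg", t, site, spec.pk, spec.pd_params)
            y = _apply_noise(y, spec.sigma.get("bdg", 0.0), rng)
            datasets.append(ClinicalDataset(
                name=f"bdg_fbm{site:g}", kind="bdg", regimen="weekly70",
                t=t, values=y, unit="%", fbm=site))

    if out_dir is not None:
        from .io import write_clinical_csv
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            write_clinical_csv(ds, out_dir / f"{ds.name}.csv")
    return datasets


__all__ = ["SyntheticSpec", "generate_synthetic_clinical"]
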