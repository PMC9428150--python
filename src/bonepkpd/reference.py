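"""Published fitted constants for the alendronate compartmental models.

These are the literature point estimates for each PK topology (fitted to
single-dose serum, short-term urine and long-term IV urine data) and for the
six coupled PK-PD model variants.  They are shipped as named inputs so
simulations and fixtures can be parameterized without refitting.
"""

from __future__ import annotations

from .pk import PKParams, Topology

#: PK-only fits per topology (rate constants 1/day, V_c in L)
PK_TOPOLOGY_FITS: dict[Topology, dict] = {
    Topology.ONE_C: dict(k_CC=19.03, k_el_urine=15.15, k_BC=9.02,
                         V_c=3.78, F=4.37e-3),
    Topology.TWO_C: dict(k_CC=17.26, k_el_urine=15.34, k_BC=11.64,
                         k_el_BC=1.90e-3, V_c=3.73, F=4.84e-3),
    Topology.THREE_C_SERIES: dict(k_CC=25.49, k_el_urine=9.44, k_BC=8.95,
                                  k_el_BC=2.40e-2, k_IC=2.60e-2,
                                  k_el_IC=9.36e-4, V_c=6.07, F=5.32e-3),
    Topology.THREE_C_PARALLEL: dict(k_CC=16.33, k_el_urine=14.80, k_NCT=6.60,
                                    k_el_NCT=4.95e-2, k_BC=7.46,
                                    k_el_BC=4.38e-4, V_c=3.85, F=5.35e-3),
    Topology.FOUR_C: dict(k_CC=16.21, k_el_urine=14.90, k_NCT=6.67,
                          k_el_NCT=4.91e-2, k_BC=7.52, k_el_BC=4.43e-4,
                          k_IC=1.01e-5, k_el_IC=9.08e-3, V_c=3.82, F=5.36e-3),
}


def pk_params(topology: Topology) -> PKParams:
    """The published PK fit for a topology as a :class:`PKParams`."""
    return PKParams(**PK_TOPOLOGY_FITS[topology])


#: coupled-model fits: PK constants (3C-parallel without k_el_BC, which the
#: osteoclast coupling replaces) plus the drug-effect constants.
#: pi_* in day/mM as printed; f_sat in mM (None: no saturation fitted).
PKPD_VARIANT_FITS: dict[str, dict] = {
    "pkpd1": dict(pk=dict(k_CC=16.33, k_el_urine=14.80, k_NCT=6.81,
                          k_el_NCT=4.90e-2, k_BC=7.39, V_c=3.84, F=5.36e-3),
                  pi_act=12.98, pi_rep=14.31, f_sat=7.72e-2),
    "pkpd2": dict(pk=dict(k_CC=16.33, k_el_urine=14.80, k_NCT=6.84,
                          k_el_NCT=4.44e-2, k_BC=7.33, V_c=3.85, F=5.36e-3),
                  pi_act=0.0, pi_rep=20.30, f_sat=7.72e-2),
    "pkpd3": dict(pk=dict(k_CC=16.33, k_el_urine=14.80, k_NCT=6.66,
                          k_el_NCT=4.77e-2, k_BC=7.53, V_c=3.85, F=5.36e-3),
                  pi_act=32.91, pi_rep=0.0, f_sat=1.07e-1),
    "pkpd4": dict(pk=dict(k_CC=28.70, k_el_urine=10.61, k_NCT=6.97,
                          k_el_NCT=1.34e-3, k_BC=2.61e-5, V_c=5.33,
                          F=4.34e-3),
                  pi_act=16.69e5, pi_rep=27.68e4, f_sat=None),
    "pkpd5": dict(pk=dict(k_CC=11.28, k_el_urine=26.54, k_NCT=19.11,
                          k_el_NCT=1.51e-3, k_BC=2.93e-4, V_c=2.06,
                          F=4.87e-3),
                  pi_act=34.45e4, pi_rep=48.29e3, f_sat=None),
    "pkpd6": dict(pk=dict(k_CC=18.92, k_el_urine=10.97, k_NCT=8.40,
                          k_el_NCT=2.07e-3, k_BC=8.67, V_c=5.22, F=6.41e-3),
                  pi_act=11.80, pi_rep=3.85, f_sat=1.79e-1),
}

__all__ = ["PK_TOPOLOGY_FITS", "pk_params", "PKPD_VARIANT_FITS"]
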