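"""Simulation conditions and kinetic parameter defaults for the pathway model.

Concentrations are nM, time is seconds internally (hours at the interface).
The quantitative parameter values are package defaults chosen to satisfy the
documented calibration constraints (see docs/methods.md), most importantly:

* wild-type RAS, low RTK activity: stationary RAS-GTP ~ 25 nM;
* oncogenic RAS (RAS-GAP rate divided by 10): stationary RAS-GTP ~ 250 nM.

With a saturable GAP (Michaelis constant ``km_gap``) and a constant basal
nucleotide-exchange rate, the two constraints pin ``km_gap`` exactly:

    k_gef*(750-25)*(km+25) = 25*V   and   k_gef*(750-250)*(km+250) = 25*V
    =>  km_gap = 475 nM,  v_gap_max = 14500 * k_gef_basal.

Every value can be overridden per run; ``SimulationCondition`` carries the
condition-level switches (abundances, RAS mutational status, RTK level, doses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import InvalidParameterError

ISOFORMS = ("A", "B", "C")  # ARAF, BRAF, CRAF


@dataclass(frozen=True)
class SimulationCondition:
    """Condition-level inputs: protein abundances, RAS status, RTK level, doses."""

    araf: float = 50.0
    braf: float = 50.0
    craf: float = 50.0
    mek_total: float = 700.0
    erk_total: float = 400.0
    ras_total: float = 750.0
    sos_total: float = 100.0
    rtk_activity: str = "low"  # "low" | "high"
    ras_status: str = "wild-type"  # "wild-type" | "mutant"
    dose1: float = 0.0  # inhibitor slot a, nM
    dose2: float = 0.0  # inhibitor slot b, nM

    def __post_init__(self) -> None:
        for name in ("araf", "braf", "craf", "mek_total", "erk_total",
                     "ras_total", "sos_total", "dose1", "dose2"):
            value = getattr(self, name)
            if value < 0 or not np.isfinite(value):
                raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")
        if self.rtk_activity not in ("low", "high"):
            raise InvalidParameterError(
                f"rtk_activity must be 'low' or 'high', got {self.rtk_activity!r}"
            )
        if self.ras_status not in ("wild-type", "mutant"):
            raise InvalidParameterError(
                f"ras_status must be 'wild-type' or 'mutant', got {self.ras_status!r}"
            )

    @property
    def raf_abundance(self) -> dict[str, float]:
        return {"A": self.araf, "B": self.braf, "C": self.craf}

    def with_doses(self, dose1: float | None = None,
                   dose2: float | None = None) -> "SimulationCondition":
        return replace(self,
                       dose1=self.dose1 if dose1 is None else float(dose1),
                       dose2=self.dose2 if dose2 is None else float(dose2))


@dataclass(frozen=True)
class PathwayParameters:
    """Kinetic and thermodynamic defaults of the pathway model (nM, 1/s)."""

    # --- RAS module (calibrated, see module docstring) ---
    k_gef_basal: float = 1e-4      # basal RAS-GDP -> RAS-GTP exchange, 1/s
    km_gap: float = 475.0          # GAP saturation constant, nM
    v_gap_max: float = 1.45        # GAP Vmax at baseline, nM/s (14500*k_gef_basal)
    mutant_gap_scale: float = 0.1  # RAS-GAP rate divided by 10 in oncogenic RAS

    # --- RTK / GRB2-SOS module ---
    k_sos_recruit: float = 1e-4    # SOS cytoplasm -> membrane, 1/s (low RTK)
    k_sos_release: float = 1e-2    # SOS membrane -> cytoplasm, 1/s
    ksos_transl_scale: float = 5.0  # SOS-GRB2 equilibrium scaled 5-fold
    rtk_high_mult: float = 50.0    # recruitment multiplier at high RTK activity
    k_gef_sos: float = 1e-6        # SOS_mem-driven exchange, 1/nM/s
    k_fb_sos: float = 1e-5         # ppERK feedback phosphorylation of SOS, 1/nM/s
    k_sos_dephos: float = 1e-3     # SOS dephosphorylation, 1/s

    # --- RAF recruitment and dimerization ---
    k_rbd: float = 10.0            # RAS-GTP : RAF-RBD dissociation constant, nM
    kon_rbd: float = 0.01          # RBD association rate, 1/nM/s
    kdim0: float = 3e6             # cytosolic RAF dimerization Kd, nM (negligible)
    kon_dim: float = 0.01          # dimer association rate, 1/nM/s
    c_mem: float = 30.0            # dimerization enhancement per RAS-bound protomer
    # pairwise Kd multipliers: ARAF has the weakest dimer interface, so
    # ARAF-containing dimers are rare at baseline but still recruited by
    # dimer-promoting inhibitors
    dimer_kd_mult: dict = field(default_factory=lambda: {
        frozenset({"A"}): 10.0, frozenset({"A", "B"}): 5.0,
        frozenset({"A", "C"}): 5.0, frozenset({"B"}): 0.3,
    })

    # --- inhibitor binding ---
    kon_inh: float = 0.1           # inhibitor association rate, 1/nM/s
    phi: float = 0.5               # kinetic split of equilibrium-constant changes
    # isoform-selectivity: Kd multiplier per (inhibitor type, RAF isoform).
    # ARAF's atypical pocket binds alphaC-IN inhibitors (Types I, II) poorly;
    # the Type I1/2 preset is BRAF-selective (vemurafenib-like) and binds
    # CRAF weakly while tolerating ARAF's pocket.
    isoform_kd_penalty: dict = field(default_factory=lambda: {
        "I": {"A": 3.0, "B": 1.0, "C": 1.0},
        "II": {"A": 30.0, "B": 1.0, "C": 1.0},
        "I_half": {"A": 0.3, "B": 1.0, "C": 10.0},
    })  # BRAF is also the strongest homodimerizer (dimer_kd_mult {B} < 1)

    # --- RAF phosphosites ---
    k_actp: float = 0.01           # NtA activation phosphorylation in dimers, 1/s
    k_actdp: float = 1e-3          # activation-site dephosphorylation, 1/s
    k_fb_raf: float = 1e-5         # ppERK feedback phosphorylation of RAF, 1/nM/s
    k_fb_dephos: float = 1e-3      # feedback-site dephosphorylation, 1/s
    k_inh_phos: float = 1e-4       # constitutive inhibitory-site phosphorylation, 1/s
    k_inh_dephos: float = 1e-3     # inhibitory-site dephosphorylation, 1/s

    # --- catalytic activities (dimensionless weights) ---
    # BRAF monomers are autoinhibited (signal mainly as dimer protomers);
    # CRAF carries most of the RAS-bound monomer activity; ARAF monomers are
    # catalytically silent
    act_mono: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.05, "C": 0.25})
    act_dimer: float = 1.0         # fully competent dimer protomer
    act_dimer_unphos: float = 0.15  # ARAF/CRAF dimer protomer before NtA phosphorylation
    act_transactivation: float = 3.0  # boost of the free protomer when the
    #                                   partner protomer is inhibitor-bound

    # --- MEK/ERK tier ---
    k_mek: float = 2.5e-4          # RAF activity unit -> MEK phosphorylation, 1/nM/s
    k_mek_dephos: float = 0.02     # 1/s
    k_erk: float = 5e-5            # ppMEK -> ERK phosphorylation, 1/nM/s
    k_erk_dephos: float = 0.02     # 1/s

    def gef_rate(self, rtk_activity: str) -> float:
        """Basal exchange rate; the SOS-membrane contribution is a reaction."""
        return self.k_gef_basal

    def sos_recruit_rate(self, rtk_activity: str) -> float:
        mult = self.rtk_high_mult if rtk_activity == "high" else 1.0
        return self.k_sos_recruit * self.ksos_transl_scale * mult

    def gap_vmax(self, ras_status: str) -> float:
        scale = self.mutant_gap_scale if ras_status == "mutant" else 1.0
        return self.v_gap_max * scale
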