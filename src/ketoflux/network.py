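"""Isotopomer network of the two-pool ketone model and its steady-state
forward simulator.

The network has eleven reactions: tracer infusions (Rinf), endogenous
appearance (Ra), interconversion (Ri), disposal (Rd) for each ketone,
plus three sampling reactions with zero stoichiometry that expose the
blood labeling to the measurement without perturbing the mass balances.
Atom transitions track the four carbons (A-D, capital letters) and the
C3 hydrogen (a, lower case) that distinguishes BHB from AcAc; the
derivatization step writes a deuterium onto that position of every
sampled AcAc molecule, which is what shifts AcAc-derived signal to odd
masses.

Because no reaction cleaves or condenses the tracked carbon skeleton,
the isotopologue balances close at the level of whole-molecule MIDs: for
each carbon mass the two blood pools satisfy a 2x2 linear system, which
the simulator solves exactly.  The generic atom-map validation is kept so
the network remains the single source of truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .mid import MID, normalize
from .twopool import FluxState

__all__ = [
    "TracerProtocol",
    "Reaction",
    "NetworkModel",
    "build_network",
    "simulate_steady_state",
    "simulate_combined_mid",
    "adjust_infusion_rate",
]

#: carbon masses reachable with [3,4-13C2]AcAc and [U-13C4]BHB tracers
CARBON_MASSES = (0, 2, 4)

# default infusate labeling: pure tracers.  The AcAc tracer carries two
# 13C (M+2), the BHB tracer four (M+4), over carbon masses {0, 2, 4}.
PURE_ACAC_INFUSATE = MID(np.array([0.0, 1.0, 0.0]))
PURE_BHB_INFUSATE = MID(np.array([0.0, 0.0, 1.0]))


@dataclass(frozen=True)
class TracerProtocol:
    """Dual-tracer infusion protocol.

    Rates are umol/h per animal.  ``infusate_acac_mid`` and
    ``infusate_bhb_mid`` give the tracer labeling over carbon masses
    {0, 2, 4} and default to chemically pure tracers.  Prime-infusion
    fields are recorded metadata only: the steady-state model does not
    use them.  If a measured infusate concentration is supplied the
    effective infusion rate is scaled by measured/theoretical, the
    correction required when AcAc tracer is lost during infusate
    neutralization.
    """

    rinf_acac: float = 1.91
    rinf_bhb: float = 2.08
    infusate_acac_mid: MID = PURE_ACAC_INFUSATE
    infusate_bhb_mid: MID = PURE_BHB_INFUSATE
    prime_rate_acac: float = 4.77
    prime_rate_bhb: float = 5.21
    prime_duration_min: float = 10.0
    infusion_duration_min: float = 80.0
    measured_conc_acac: float | None = None
    theoretical_conc_acac: float | None = None
    measured_conc_bhb: float | None = None
    theoretical_conc_bhb: float | None = None

    def __post_init__(self) -> None:
        if self.rinf_acac <= 0 or self.rinf_bhb <= 0:
            raise ValueError("infusion rates must be positive")
        if len(self.infusate_acac_mid) != 3 or len(self.infusate_bhb_mid) != 3:
            raise ValueError("infusate MIDs span carbon masses {0, 2, 4}")

    @property
    def effective_rinf_acac(self) -> float:
        if self.measured_conc_acac is None:
            return self.rinf_acac
        return adjust_infusion_rate(
            self.rinf_acac, self.measured_conc_acac, self.theoretical_conc_acac
        )

    @property
    def effective_rinf_bhb(self) -> float:
        if self.measured_conc_bhb is None:
            return self.rinf_bhb
        return adjust_infusion_rate(
            self.rinf_bhb, self.measured_conc_bhb, self.theoretical_conc_bhb
        )


def adjust_infusion_rate(
    nominal: float, measured_conc: float, theoretical_conc: float
) -> float:
    """Correct a nominal infusion rate for infusate concentration loss.

    The AcAc tracer is prepared by alkaline hydrolysis of its ethyl ester
    and can be partially lost during neutralization, so the achieved
    infusate concentration must be assayed: the delivered rate is
    ``nominal * measured / theoretical``.
    """
    if theoretical_conc is None or theoretical_conc <= 0:
        raise ValueError("theoretical infusate concentration must be positive")
    if measured_conc is None or measured_conc <= 0:
        raise ValueError("measured infusate concentration must be positive")
    return nominal * measured_conc / theoretical_conc


@dataclass(frozen=True)
class Reaction:
    """One network reaction with its atom transitions.

    ``educts``/``products`` are ``(coefficient, species, atoms)`` tuples
    where ``atoms`` is the transition string: capital letters are carbon
    positions, lower-case letters are tracked hydrogens.  Sampling
    reactions carry coefficient 0 so they expose labeling without
    entering the mass balances.
    """

    name: str
    educts: tuple = ()
    products: tuple = ()

    def carbon_count(self, side: str) -> int:
        entries = self.educts if side == "educts" else self.products
        return sum(len(re.findall(r"[A-Z]", atoms)) for _, _, atoms in entries)

    def hydrogen_labels(self, side: str) -> list[str]:
        entries = self.educts if side == "educts" else self.products
        out = []
        for _, species, atoms in entries:
            for h in re.findall(r"[a-z]", atoms):
                out.append(f"{species}:{h}")
        return out


#: Species whose hydrogen position 'a' carries deuterium.  Only the
#: derivatization reagent is labeled; every in vivo hydrogen source
#: (body water, the BHB C3 hydrogen released on oxidation) is unlabeled,
#: so in vivo mass shifts are carbon-only and the sample-prep deuterium
#: is a deterministic +1 on the AcAc-derived fraction.
DEUTERATED_SPECIES = frozenset({"D.h2o"})


@dataclass(frozen=True)
class NetworkModel:
    """The eleven-reaction two-pool network with atom maps."""

    reactions: tuple = ()
    balanced_species: tuple = ("AcAc.blood", "BHB.blood")

    @property
    def names(self) -> tuple:
        return tuple(r.name for r in self.reactions)

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    def validate(self) -> None:
        """Check carbon conservation of every atom map and the zero
        stoichiometry of the sampling reactions."""
        for r in self.reactions:
            if any(s == "SINK" for _, s, _ in r.products):
                continue  # terminal export: atoms leave the tracked system
            if r.products and r.educts:
                ne, np_ = r.carbon_count("educts"), r.carbon_count("products")
                if ne != np_:
                    raise ValueError(
                        f"reaction {r.name}: {ne} educt carbons vs {np_} "
                        "product carbons"
                    )
        for name in ("Rs BHB", "Rs AcAc"):
            r = self.reaction(name)
            coefs = [c for c, s, _ in r.educts if s.endswith(".blood")]
            if coefs != [0]:
                raise ValueError(f"sampling reaction {name} must have zero "
                                 "stoichiometry on the blood pool")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Stoichiometry of the mass-carrying fluxes over the balanced
        (blood) species.  Zero-stoichiometry sampling reactions do not
        appear."""
        flux_names = [r.name for r in self.reactions
                      if not r.name.startswith("Rs") and r.name != "Sink"]
        mat = np.zeros((len(self.balanced_species), len(flux_names)))
        for j, name in enumerate(flux_names):
            r = self.reaction(name)
            for coef, species, _ in r.educts:
                if species in self.balanced_species:
                    mat[self.balanced_species.index(species), j] -= coef
            for coef, species, _ in r.products:
                if species in self.balanced_species:
                    mat[self.balanced_species.index(species), j] += coef
        return mat

    def free_flux_dimension(self) -> int:
        """Independent adjustable parameters of the labeling model: the
        mass-carrying fluxes minus the blood-node balances, plus one for
        the sampling split (the AcAc:BHB pool ratio)."""
        mat = self.stoichiometric_matrix()
        n_fluxes = mat.shape[1]
        rank = int(np.linalg.matrix_rank(mat))
        return n_fluxes - rank + 1


def build_network() -> NetworkModel:
    """Construct and validate the two-pool ketone network.

    Transition strings follow the convention: carbons A-D, the C3
    hydrogen a.  AcAc (ABCD) gains that hydrogen on reduction to BHB
    (AaBCD); the in vivo reduction draws it from body water while the
    sample-prep reduction draws a deuterium from the NaB(2H)4 reagent.
    """
    rxns = (
        Reaction("Rinf BHB",
                 ((1, "BHB.inf", "AaBCD"),), ((1, "BHB.blood", "AaBCD"),)),
        Reaction("Rinf AcAc",
                 ((1, "AcAc.inf", "ABCD"),), ((1, "AcAc.blood", "ABCD"),)),
        Reaction("Ra BHB",
                 ((1, "BHB.source", "AaBCD"),), ((1, "BHB.blood", "AaBCD"),)),
        Reaction("Ra AcAc",
                 ((1, "AcAc.source", "ABCD"),), ((1, "AcAc.blood", "ABCD"),)),
        Reaction("Ri BHB",
                 ((1, "BHB.blood", "AaBCD"),),
                 ((1, "AcAc.blood", "ABCD"), (1, "H.bhb", "a"))),
        Reaction("Ri AcAc",
                 ((1, "AcAc.blood", "ABCD"), (1, "H.h2o", "a")),
                 ((1, "BHB.blood", "AaBCD"),)),
        Reaction("Rd BHB",
                 ((1, "BHB.blood", "AaBCD"),), ((1, "BHB.tissue", "AaBCD"),)),
        Reaction("Rd AcAc",
                 ((1, "AcAc.blood", "ABCD"),), ((1, "AcAc.tissue", "ABCD"),)),
        Reaction("Rs BHB",
                 ((0, "BHB.blood", "AaBCD"),), ((1, "BHB.s", "AaBCD"),)),
        Reaction("Rs AcAc",
                 ((0, "AcAc.blood", "ABCD"), (1, "D.h2o", "a")),
                 ((1, "BHB.s", "AaBCD"),)),
        Reaction("Sink",
                 ((1, "BHB.s", "AaBCD"),), ((1, "SINK", ""),)),
    )
    model = NetworkModel(reactions=rxns)
    model.validate()
    _assert_hydrogen_reduction(model)
    return model


def _assert_hydrogen_reduction(model: NetworkModel) -> None:
    """Verify that the full hydrogen bookkeeping reduces to a carbon-only
    in vivo model plus a deterministic +1 on sampled AcAc.

    Every hydrogen entering a blood pool in vivo must come from an
    unlabeled source; the only deuterated source may appear in the
    zero-stoichiometry sampling path.
    """
    for r in model.reactions:
        mass_carrying = all(c != 0 for c, _, _ in r.educts) if r.educts else True
        for _, species, atoms in r.educts:
            if species in DEUTERATED_SPECIES and mass_carrying:
                raise AssertionError(
                    f"deuterated source {species} feeds the in vivo network "
                    f"via {r.name}; mass shifts would not be carbon-only"
                )
    sampling = model.reaction("Rs AcAc")
    if not any(s in DEUTERATED_SPECIES for _, s, _ in sampling.educts):
        raise AssertionError(
            "sampled AcAc must acquire the derivatization deuterium"
        )


def simulate_steady_state(
    flux: FluxState, protocol: TracerProtocol
) -> tuple[MID, MID]:
    """Steady-state carbon-label MIDs of the blood AcAc and BHB pools.

    For each carbon mass m the label balance at the two pools is a 2x2
    linear system: pool outflow (disposal + interconversion out) carries
    the pool's own labeling, inflows are the infusate, the unlabeled
    endogenous source (mass 0 only) and the partner pool's labeling via
    interconversion.  Returns ``(acac_blood_mid, bhb_blood_mid)`` over
    masses {0, 2, 4}.
    """
    flux.check_balanced()
    arr = flux.as_array()
    if (arr < 0).any():
        raise ValueError(f"negative flux in {flux}; forward simulation "
                         "requires a physiological flux state")
    out_a = flux.rd_acac + flux.ri_acac
    out_b = flux.rd_bhb + flux.ri_bhb
    if out_a <= 0 or out_b <= 0:
        raise ValueError("each pool needs positive outflow at steady state")
    mat = np.array([[out_a, -flux.ri_bhb], [-flux.ri_acac, out_b]])
    x_a = np.empty(3)
    x_b = np.empty(3)
    inf_a = protocol.infusate_acac_mid.fractions
    inf_b = protocol.infusate_bhb_mid.fractions
    r_a = protocol.effective_rinf_acac
    r_b = protocol.effective_rinf_bhb
    for i, m in enumerate(CARBON_MASSES):
        rhs = np.array([
            r_a * inf_a[i] + flux.ra_acac * (m == 0),
            r_b * inf_b[i] + flux.ra_bhb * (m == 0),
        ])
        x_a[i], x_b[i] = np.linalg.solve(mat, rhs)
    return normalize(x_a), normalize(x_b)


def simulate_combined_mid(flux: FluxState, protocol: TracerProtocol) -> MID:
    """Six-channel [2H]BHB MID produced by the sample-prep derivatization.

    A fraction ``p = pool_ratio_acac`` of the sampled signal is
    AcAc-derived; each of those molecules gains the derivatization
    deuterium (+1 mass).  Even channels carry the BHB labeling weighted
    by (1 - p), odd channels the AcAc labeling weighted by p.
    """
    p = flux.pool_ratio_acac
    if not 0.0 < p < 1.0:
        raise ValueError(f"pool_ratio_acac={p} must lie in (0, 1) for both "
                         "ketone signals to exist")
    x_a, x_b = simulate_steady_state(flux, protocol)
    combined = np.empty(6)
    combined[0::2] = (1.0 - p) * x_b.fractions
    combined[1::2] = p * x_a.fractions
    return normalize(combined)
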