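"""Mass-isotopomer distributions and the derivatization-encoded ketone MID.

A blood sample treated with NaB(2H)4 converts labile acetoacetate (AcAc)
into a deuterium-tagged beta-hydroxybutyrate (BHB), shifting every
AcAc-derived molecule up by one nominal mass unit.  The single measured
BHB isotopologue envelope (M+0 ... M+5) therefore encodes two analytes at
once: even mass shifts originate from plasma BHB, odd mass shifts from
plasma AcAc.  This module provides the MID container, natural-abundance
convolution/correction, and the odd/even decoding that recovers the
individual AcAc and BHB labeling patterns together with the AcAc share of
the total ketone signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MID",
    "IonFormula",
    "DecodedKetones",
    "EnrichmentSet",
    "MIDError",
    "normalize",
    "isotope_envelope",
    "convolution_matrix",
    "convolve_natural_abundance",
    "correct_natural_abundance",
    "decode_combined_mid",
    "enrichments_from_decoded",
]

#: Natural heavy-isotope abundances (probability that one atom of the
#: element carries the listed mass shift).
ABUNDANCE_13C = 0.0107
ABUNDANCE_2H = 0.000115
ABUNDANCE_17O = 0.00038
ABUNDANCE_18O = 0.00205

_NORM_TOL = 1e-9


class MIDError(ValueError):
    """Degenerate or invalid mass-isotopomer distribution."""


@dataclass(frozen=True)
class MID:
    """Mass-isotopomer distribution over nominal mass shifts M+0 ... M+k.

    ``fractions[i]`` is the mol fraction of the isotopologue with nominal
    mass shift ``+i``.  Fractions are non-negative and sum to one.
    """

    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise MIDError("MID requires a non-empty 1-D fraction vector")
        if np.any(arr < 0):
            raise MIDError(f"negative MID fraction in {arr}")
        if abs(arr.sum() - 1.0) > _NORM_TOL:
            raise MIDError(f"MID fractions sum to {arr.sum()!r}, not 1")
        object.__setattr__(self, "fractions", arr)

    def __len__(self) -> int:
        return self.fractions.size

    def __getitem__(self, mass_shift: int) -> float:
        return float(self.fractions[mass_shift])

    def __eq__(self, other) -> bool:  # value semantics
        return isinstance(other, MID) and np.array_equal(
            self.fractions, other.fractions
        )

    def allclose(self, other: "MID", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and np.allclose(
            self.fractions, other.fractions, rtol=0.0, atol=atol
        )


def normalize(fractions) -> MID:
    """Scale a non-negative vector onto the unit simplex.

    Raises :class:`MIDError` if the vector has no signal (all zeros) or a
    negative entry.
    """
    arr = np.asarray(fractions, dtype=float)
    if np.any(arr < 0):
        raise MIDError(f"cannot normalize vector with negative entries: {arr}")
    total = arr.sum()
    if total <= 0:
        raise MIDError("cannot normalize an all-zero MID")
    return MID(arr / total)


@dataclass(frozen=True)
class IonFormula:
    """Elemental composition of the measured ion used for natural-abundance
    bookkeeping.

    ``elements`` maps an element label to ``(count, heavy_abundance,
    mass_shift)``: the number of atoms subject to correction, the natural
    probability of the heavy isotope, and its nominal mass shift.  Atoms
    that are deliberately labeled (tracer carbons, the derivatization
    deuterium) are excluded from the counts.
    """

    elements: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (count, abundance, shift) in self.elements.items():
            if count < 0:
                raise ValueError(f"negative atom count for {name}")
            if not 0.0 <= abundance < 1.0:
                raise ValueError(f"abundance for {name} outside [0, 1)")
            if shift < 1:
                raise ValueError(f"mass shift for {name} must be >= 1")

    @classmethod
    def carbon_skeleton(cls, n_carbon: int = 4,
                        abundance: float = ABUNDANCE_13C) -> "IonFormula":
        """Carbon-only correction formula (the dominant contribution for
        the BHB product ion)."""
        return cls({"C": (n_carbon, abundance, 1)})

    @classmethod
    def bhb_ion(cls, fragment: str = "product") -> "IonFormula":
        """Formula for the measured BHB ion.

        ``fragment='product'`` uses the m/z 87 product ion (C4H7O2 minus
        the tracked skeleton hydrogens), ``fragment='precursor'`` the
        m/z 105 precursor (C4H9O3).  In both cases the four carbons
        dominate; H and O contribute at the 1e-4 level.
        """
        if fragment == "product":
            h, o = 6, 2
        elif fragment == "precursor":
            h, o = 8, 3
        else:
            raise ValueError(f"unknown fragment {fragment!r}")
        return cls({
            "C": (4, ABUNDANCE_13C, 1),
            "H": (h, ABUNDANCE_2H, 1),
            "O17": (o, ABUNDANCE_17O, 1),
            "O18": (o, ABUNDANCE_18O, 2),
        })


def isotope_envelope(formula: IonFormula, max_shift: int | None = None) -> np.ndarray:
    """Theoretical isotope distribution of the formula's unlabeled atoms.

    The envelope is the convolution of one two-point distribution per atom
    (light isotope at +0, heavy isotope at its mass shift), i.e. a product
    of independent binomials.  Returns a vector starting at mass shift 0.
    """
    env = np.array([1.0])
    for count, abundance, shift in formula.elements.values():
        atom = np.zeros(shift + 1)
        atom[0] = 1.0 - abundance
        atom[shift] = abundance
        for _ in range(count):
            env = np.convolve(env, atom)
    if max_shift is not None:
        env = env[: max_shift + 1]
    return env


def convolution_matrix(formula: IonFormula, n: int) -> np.ndarray:
    """Square lower-triangular matrix C with raw = C @ corrected over ``n``
    mass channels."""
    env = isotope_envelope(formula, max_shift=n - 1)
    mat = np.zeros((n, n))
    for j in range(n):
        take = min(env.size, n - j)
        mat[j : j + take, j] = env[:take]
    return mat


def convolve_natural_abundance(mid: MID, formula: IonFormula) -> MID:
    """Forward-convolve a labeled MID with the natural isotope envelope.

    The output is longer than the input by the significant envelope width
    and is renormalized (the envelope itself sums to 1 up to floating
    error, so this is a no-op beyond rounding).
    """
    env = isotope_envelope(formula)
    out = np.convolve(mid.fractions, env)
    return normalize(out)


def correct_natural_abundance(
    raw: MID,
    formula: IonFormula,
    clip_warn_threshold: float = 0.005,
) -> MID:
    """Remove natural-abundance contributions from a measured MID.

    Inverts the lower-triangular convolution matrix over the measured mass
    channels.  Small negative fractions produced by measurement noise are
    clipped to zero and the vector renormalized; clips larger than
    ``clip_warn_threshold`` trigger a warning because they indicate a
    distorted envelope rather than noise.
    """
    n = len(raw)
    mat = convolution_matrix(formula, n)
    diag = np.diag(mat)
    if np.any(diag <= 0) or np.linalg.cond(mat) > 1e12:
        raise np.linalg.LinAlgError(
            "natural-abundance correction matrix is singular; check the ion "
            f"formula {formula.elements!r}"
        )
    corrected = np.linalg.solve(mat, raw.fractions)
    negative = corrected < 0
    if negative.any():
        worst = float(-corrected[negative].min())
        if worst > clip_warn_threshold:
            warnings.warn(
                f"natural-abundance correction clipped a fraction of magnitude "
                f"{worst:.4g} (> {clip_warn_threshold}); the measured envelope "
                "is inconsistent with the ion formula",
                stacklevel=2,
            )
        corrected = np.clip(corrected, 0.0, None)
    return normalize(corrected)


@dataclass(frozen=True)
class DecodedKetones:
    """Individual ketone labeling recovered from the combined [2H]BHB MID.

    ``bhb_mid`` and ``acac_mid`` are carbon-label MIDs over mass shifts
    {0, 2, 4}; ``acac_fraction`` is the AcAc share of the total ketone
    signal (the odd-mass share of the combined MID).
    """

    bhb_mid: MID
    acac_mid: MID
    acac_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.acac_fraction <= 1.0:
            raise MIDError("acac_fraction outside [0, 1]")
        if len(self.bhb_mid) != 3 or len(self.acac_mid) != 3:
            raise MIDError("decoded ketone MIDs span masses {0, 2, 4}")


def decode_combined_mid(combined: MID) -> DecodedKetones:
    """Split the combined six-channel MID into per-ketone labeling.

    Even channels (M+0, M+2, M+4) are plasma BHB; odd channels (M+1, M+3,
    M+5) are plasma AcAc shifted by the derivatization deuterium, so they
    map back to AcAc carbon masses (0, 2, 4).  Each sub-MID is
    renormalized; the odd-mass sum is the AcAc pool fraction.
    """
    if len(combined) != 6:
        raise MIDError(f"combined ketone MID has 6 channels, got {len(combined)}")
    even = combined.fractions[[0, 2, 4]]
    odd = combined.fractions[[1, 3, 5]]
    acac_fraction = float(odd.sum())
    if odd.sum() <= 0:
        raise MIDError(
            "no odd-mass signal: AcAc pool undetectable, AcAc enrichments "
            "are undefined"
        )
    if even.sum() <= 0:
        raise MIDError(
            "no even-mass signal: BHB pool undetectable, BHB enrichments "
            "are undefined"
        )
    return DecodedKetones(
        bhb_mid=normalize(even),
        acac_mid=normalize(odd),
        acac_fraction=acac_fraction,
    )


@dataclass(frozen=True)
class EnrichmentSet:
    """Steady-state tracer enrichments of the two blood ketone pools.

    Following the conventional A/B/C/D notation of the two-pool matrix
    method: A and C are the M+2 and M+4 enrichments of AcAc, B and D the
    M+2 and M+4 enrichments of BHB.  M+2 derives from the [3,4-13C2]AcAc
    tracer, M+4 from the [U-13C4]BHB tracer.
    """

    acac_m2: float  # A
    bhb_m2: float   # B
    acac_m4: float  # C
    bhb_m4: float   # D

    def __post_init__(self) -> None:
        for name in ("acac_m2", "bhb_m2", "acac_m4", "bhb_m4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"enrichment {name}={v} outside [0, 1]")
        if self.acac_m2 + self.acac_m4 > 1.0 + _NORM_TOL:
            raise ValueError("AcAc M+2 and M+4 enrichments exceed 1")
        if self.bhb_m2 + self.bhb_m4 > 1.0 + _NORM_TOL:
            raise ValueError("BHB M+2 and M+4 enrichments exceed 1")


def enrichments_from_decoded(decoded: DecodedKetones) -> EnrichmentSet:
    """Extract the A/B/C/D enrichments used by the matrix method."""
    return EnrichmentSet(
        acac_m2=decoded.acac_mid[1],
        bhb_m2=decoded.bhb_mid[1],
        acac_m4=decoded.acac_mid[2],
        bhb_m4=decoded.bhb_mid[2],
    )
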