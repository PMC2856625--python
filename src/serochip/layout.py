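"""Array layout: which analytes are printed where, and how often.

An allergen microarray in this design carries a panel of allergen extracts
printed in triplicate, negative-control spots (human serum albumin and print
buffer), and serial-dilution standard curves of purified IgE, IgG and IgA.
Twelve arrays fit on one slide.  The layout object is the single source of
truth for which spot labels are expected on an array and with how many
replicates; everything downstream (validation, calibration, aggregation)
resolves spot names against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import DesignError

# Spot roles
ALLERGEN = "allergen"
CONTROL = "control"
STANDARD = "standard"
UNMAPPED = "unmapped"

#: Pollen species abbreviations (6 grasses, 2 weeds, 14 trees).
POLLEN_SPECIES = (
    "Ber", "Blu", "Jhn", "Orc", "Rye", "Tim",          # grasses
    "Mug", "Rag",                                       # weeds
    "Ald", "Ash", "Bir", "Ced", "Cot", "Eld", "Elm",    # trees
    "Mul", "Rok", "Wok", "Olv", "Pec", "Syc", "Wal",
)

#: Non-pollen commercial extracts.
NON_POLLEN = ("Asp n", "Alt a", "Der f", "Der p", "Acr", "Gcr", "Cat", "Dog", "Dst")

#: Recombinant major allergens.
RECOMBINANT = ("Amb a 1", "Bet v 1", "Phl p 2", "Alt a 1", "Der p 1")

#: Allergen-class labels used by the CV report.
CLASS_SURFACE = "surface"
CLASS_CYTOPLASM = "cytoplasm"
CLASS_POLLEN_EXTRACT = "pollen extract"
CLASS_NON_POLLEN = "non-pollen extract"
CLASS_RECOMBINANT = "recombinant"


def standard_label(isotype: str, concentration: float) -> str:
    """Canonical spot label for one point of a standard curve, e.g. ``IgE_12.5``."""
    return f"{isotype}_{concentration:g}"


@dataclass(frozen=True)
class ArrayLayout:
    """Printed content of one array.

    Parameters
    ----------
    allergen_names
        Ordered analyte labels (80 in the reference design).
    replicates_per_allergen
        Number of replicate spots per allergen (triplicate by default).
    control_names, control_replicates
        Negative-control labels and their replicate count.
    standard_isotypes, standard_concentrations, standard_replicates
        Serial-dilution standard curves, concentrations in pg/spot,
        strictly decreasing.
    arrays_per_slide
        Physical arrays per slide.
    allergen_classes
        Optional label -> class mapping (surface / cytoplasm / pollen
        extract / non-pollen extract / recombinant) used by CV reporting.
    """

    allergen_names: tuple[str, ...]
    replicates_per_allergen: int = 3
    control_names: tuple[str, ...] = ("HSA", "buffer")
    control_replicates: int = 6
    standard_isotypes: tuple[str, ...] = ("IgE", "IgG", "IgA")
    standard_concentrations: tuple[float, ...] = (
        200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.5625,
    )
    standard_replicates: int = 6
    arrays_per_slide: int = 12
    allergen_classes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.allergen_names)) != len(self.allergen_names):
            raise DesignError("allergen names must be unique")
        concs = self.standard_concentrations
        if any(c <= 0 for c in concs):
            raise DesignError("standard concentrations must be positive")
        if any(a <= b for a, b in zip(concs, concs[1:])):
            raise DesignError("standard concentrations must be strictly decreasing")
        for n in (self.replicates_per_allergen, self.control_replicates,
                  self.standard_replicates, self.arrays_per_slide):
            if n < 1:
                raise DesignError("replicate and per-slide counts must be >= 1")

    # -- label resolution -------------------------------------------------

    def expected_counts(self) -> dict[str, int]:
        """Expected replicate count per spot label on a conformant array."""
        counts: dict[str, int] = {}
        for name in self.allergen_names:
            counts[name] = self.replicates_per_allergen
        for name in self.control_names:
            counts[name] = self.control_replicates
        for iso in self.standard_isotypes:
            for conc in self.standard_concentrations:
                counts[standard_label(iso, conc)] = self.standard_replicates
        return counts

    def spot_role(self, name: str) -> str:
        """Role of a spot label: allergen, control, standard, or unmapped."""
        if name in self.allergen_names:
            return ALLERGEN
        if name in self.control_names:
            return CONTROL
        if name in self._standard_labels():
            return STANDARD
        return UNMAPPED

    def _standard_labels(self) -> frozenset[str]:
        return frozenset(
            standard_label(iso, conc)
            for iso in self.standard_isotypes
            for conc in self.standard_concentrations
        )

    def standard_concentration_of(self, name: str) -> tuple[str, float] | None:
        """Parse a standard-curve label back into (isotype, pg/spot)."""
        for iso in self.standard_isotypes:
            prefix = iso + "_"
            if name.startswith(prefix):
                try:
                    return iso, float(name[len(prefix):])
                except ValueError:
                    return None
        return None

    @property
    def spots_per_array(self) -> int:
        return sum(self.expected_counts().values())


def default_layout() -> ArrayLayout:
    """The 80-allergen reference layout.

    22 pollen species, each contributing a pollen-surface fraction, a
    cytoplasmic fraction and a commercial extract (66 analytes, suffixes
    ``_sur`` / ``_cyt`` / ``_ext``), plus 9 non-pollen commercial extracts
    and 5 recombinant major allergens.
    """
    names: list[str] = []
    classes: dict[str, str] = {}
    for sp in POLLEN_SPECIES:
        for suffix, cls in (("_sur", CLASS_SURFACE), ("_cyt", CLASS_CYTOPLASM),
                            ("_ext", CLASS_POLLEN_EXTRACT)):
            label = sp + suffix
            names.append(label)
            classes[label] = cls
    for sp in NON_POLLEN:
        names.append(sp)
        classes[sp] = CLASS_NON_POLLEN
    for sp in RECOMBINANT:
        names.append(sp)
        classes[sp] = CLASS_RECOMBINANT
    if len(names) != 80:  # pragma: no cover - structural sanity
        raise DesignError(f"reference layout must have 80 allergens, got {len(names)}")
    return ArrayLayout(allergen_names=tuple(names), allergen_classes=classes)


def small_layout(n_allergens: int = 8, replicates: int = 3) -> ArrayLayout:
    """A reduced layout for fast experiments: ``A01..Ann`` in triplicate."""
    names = tuple(f"A{i:02d}" for i in range(1, n_allergens + 1))
    classes = {n: CLASS_POLLEN_EXTRACT for n in names}
    return ArrayLayout(allergen_names=names,
                       replicates_per_allergen=replicates,
                       allergen_classes=classes)
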