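"""Trait registry for faba bean multi-environment trials.

Nine phenology, morphology and yield-component traits are tracked:

====  =========================  ======  ==================
code  name                       units   direction of merit
====  =========================  ======  ==================
DTF   days to full flowering     days    context-dependent
DTM   days to full maturity      days    context-dependent
PH    plant height               cm      higher
NOB   branches per plant         count   higher
HFP   height of first pod        cm      lower
PPN   pods per node              count   higher
PPF   pods per flower            ratio   higher
PL    pod length                 cm      higher
SPP   seeds per pod              count   higher
====  =========================  ======  ==================

The module also carries the simulator defaults: per-trait variance
components of the multi-trial mixed model, grand means, and the additive
effects of the four botanical seed-size types (paucijuga, minor, equina,
major) on each trait, with paucijuga as the reference type.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Trait:
    """One measured trait: code, long name, units and direction of merit.

    ``higher_is_better`` is the default used when a trait feeds a
    selection index without an ideotype target; it can be overridden
    per analysis.
    """

    code: str
    name: str
    units: str
    higher_is_better: bool = True
    lower: float | None = None  # hard bound enforced by the simulator
    upper: float | None = None


TRAITS: dict[str, Trait] = {
    t.code: t
    for t in [
        Trait("DTF", "days to full flowering", "days", False, lower=0.0),
        Trait("DTM", "days to full maturity", "days", False, lower=0.0),
        Trait("PH", "plant height", "cm", True, lower=0.0),
        Trait("NOB", "branches per plant", "count", True, lower=0.0),
        Trait("HFP", "height of first pod", "cm", False, lower=0.0),
        Trait("PPN", "pods per node", "count", True, lower=0.0),
        Trait("PPF", "pods per flower", "ratio", True, lower=0.0, upper=1.0),
        Trait("PL", "pod length", "cm", True, lower=0.0),
        Trait("SPP", "seeds per pod", "count", True, lower=0.0),
    ]
}

TRAIT_CODES: tuple[str, ...] = tuple(TRAITS)

#: Variance components (sigma2_g, sigma2_ge, sigma2_rc, sigma2_e) per trait
#: used as simulator defaults; these are the multi-trial REML estimates for
#: a European faba bean diversity collection.
DEFAULT_VARIANCES: dict[str, tuple[float, float, float, float]] = {
    "DTF": (16.7, 9.91, 2.19, 10.6),
    "DTM": (12.3, 20.4, 2.17, 8.49),
    "PH": (127.0, 56.2, 6.07, 45.1),
    "NOB": (0.60, 0.62, 0.03, 0.56),
    "HFP": (33.9, 13.8, 2.02, 24.2),
    "PPN": (0.04, 0.01, 0.01, 0.06),
    "PPF": (0.01, 0.01, 0.00, 0.01),
    "PL": (1.91, 0.57, 0.03, 0.64),
    "SPP": (0.12, 0.13, 0.01, 0.16),
}

#: Grand means per trait (rounded midpoints of the per-environment means
#: observed in the collection; units as in the registry).
DEFAULT_GRAND_MEANS: dict[str, float] = {
    "DTF": 80.0,
    "DTM": 120.0,
    "PH": 70.0,
    "NOB": 3.0,
    "HFP": 20.0,
    "PPN": 1.2,
    "PPF": 0.5,
    "PL": 6.83,
    "SPP": 3.0,
}

BOTANICAL_TYPES: tuple[str, ...] = ("paucijuga", "minor", "equina", "major")

#: Reference-level (paucijuga) intercepts of the botanical-type fixed-effect
#: model, per trait.
BOTANICAL_INTERCEPTS: dict[str, float] = {
    "DTF": 54.4,
    "DTM": 108.0,
    "PH": 71.28,
    "NOB": 2.76,
    "HFP": 24.1,
    "PPF": 0.35,
    "PPN": 1.65,
    "PL": 5.01,
    "SPP": 3.23,
}

#: Additive shifts of each botanical type relative to paucijuga, per trait
#: (non-significant effects included as estimated).
BOTANICAL_SHIFTS: dict[str, dict[str, float]] = {
    "minor": {
        "DTF": 1.56, "DTM": 4.17, "PH": 5.45, "NOB": 0.23, "HFP": 5.61,
        "PPF": -0.070, "PPN": -0.07, "PL": 1.03, "SPP": -0.08,
    },
    "equina": {
        "DTF": -0.97, "DTM": 1.14, "PH": -5.96, "NOB": 1.05, "HFP": 1.65,
        "PPF": 0.027, "PPN": -0.29, "PL": 1.83, "SPP": -0.37,
    },
    "major": {
        "DTF": -0.89, "DTM": 1.63, "PH": -8.36, "NOB": 1.31, "HFP": 1.24,
        "PPF": 0.015, "PPN": -0.43, "PL": 3.21, "SPP": -0.36,
    },
    "paucijuga": {c: 0.0 for c in TRAIT_CODES},
}

#: Botanical-type frequencies in the whole collection (used by the simulator
#: to assign types to genotypes; "unknown" genotypes carry no type shift).
BOTANICAL_FREQUENCIES: dict[str, float] = {
    "paucijuga": 0.05,
    "minor": 0.24,
    "equina": 0.41,
    "major": 0.17,
    "unknown": 0.13,
}

#: Transitional seed types are merged into a main type before composition
#: tables; the merge direction (first-named main type) is a package
#: convention, the convention itself being configurable.
TRANSITIONAL_MERGE: dict[str, str] = {
    "equina-major": "equina",
    "major-equina": "major",
    "equina-minor": "equina",
    "minor-paucijuga": "minor",
}

#: Default ideotype targets for the multi-trait selection index.  PPF and
#: SPP targets are the observed collection maxima; the rest are breeding
#: targets (continuous podding from 10 cm, tall but lodging-safe plants).
DEFAULT_IDEOTYPE: dict[str, float] = {
    "PH": 93.0,
    "PL": 9.0,
    "NOB": 4.9,
    "HFP": 10.0,
    "PPN": 4.12,
    "SPP": 8.33,
    "PPF": 1.0,
}


@dataclass(frozen=True)
class TraitRegistry:
    """Lookup of traits carried by a dataset, defaulting to the full set."""

    traits: dict[str, Trait] = field(default_factory=lambda: dict(TRAITS))

    def __contains__(self, code: str) -> bool:
        return code in self.traits

    def __getitem__(self, code: str) -> Trait:
        return self.traits[code]

    def codes(self) -> tuple[str, ...]:
        return tuple(self.traits)
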