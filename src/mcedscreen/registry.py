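"""Cancer-class registry: labels, expected clinical signal origins, sex restrictions.

A *cancer class* is an incidence bookkeeping unit (an organ/histology grouping of
registry codes).  Each class maps to the clinical cancer signal origin (CSO) a
tumor-of-origin classifier is expected to return for it, or to ``"none"`` for the
residual "other" grouping that has no single expected origin.  Sex restrictions
apply to *clinical* cancers only; predicted CSOs are never sex-restricted (a male
can receive a breast prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

STAGES = ("I", "II", "III", "IV")
UNSTAGED = "unstaged"
ALL_STAGES = STAGES + (UNSTAGED,)

SEXES = ("female", "male")
SMOKING_STATUSES = ("never", "former", "current")
ANY_SMOKING = "any"

NO_CSO = "none"


@dataclass(frozen=True)
class CancerClassRegistry:
    """Ordered cancer classes with their expected clinical CSO and sex restriction.

    Parameters
    ----------
    classes:
        Ordered, unique class labels.
    cso_map:
        Class label -> expected clinical CSO label, or ``"none"`` for classes
        (like "other") with no expected origin.
    sex_restriction:
        Class label -> ``"both"``, ``"female"`` or ``"male"``.  Missing entries
        default to ``"both"``.
    """

    classes: tuple[str, ...]
    cso_map: dict[str, str]
    sex_restriction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            dupes = sorted({c for c in self.classes if list(self.classes).count(c) > 1})
            raise ValueError(f"duplicate cancer class labels: {dupes}")
        missing = [c for c in self.classes if c not in self.cso_map]
        if missing:
            raise ValueError(f"classes missing a clinical CSO mapping: {missing}")
        extra = [c for c in self.cso_map if c not in self.classes]
        if extra:
            raise ValueError(f"cso_map entries for unknown classes: {extra}")
        for c, r in self.sex_restriction.items():
            if c not in self.classes:
                raise ValueError(f"sex restriction for unknown class {c!r}")
            if r not in ("both",) + SEXES:
                raise ValueError(f"invalid sex restriction {r!r} for class {c!r}")

    def restriction(self, cancer_class: str) -> str:
        return self.sex_restriction.get(cancer_class, "both")

    def allowed_for_sex(self, cancer_class: str, sex: str) -> bool:
        r = self.restriction(cancer_class)
        return r == "both" or r == sex

    @property
    def csos(self) -> tuple[str, ...]:
        """Clinical CSO labels in first-appearance order, excluding ``"none"``."""
        seen: list[str] = []
        for c in self.classes:
            o = self.cso_map[c]
            if o != NO_CSO and o not in seen:
                seen.append(o)
        return tuple(seen)

    def classes_for_cso(self, cso: str) -> tuple[str, ...]:
        return tuple(c for c in self.classes if self.cso_map[c] == cso)
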