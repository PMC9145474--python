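"""Code and medication lexicons for the three-category PAH screen.

The screen looks for any of three kinds of coded evidence: an ICD-9/10
diagnosis code for primary pulmonary hypertension, a CPT procedure code for
right heart catheterization, or a mention of a PAH-specific medication
(brand or generic name).  The exact code lists are configuration, not code:
a sensible default is shipped and everything is overridable from a YAML/JSON
config file (see :mod:`pahphen.io`).

Each lexicon entry is a screened *variable*.  By default brand and generic
medication names are separate variables (so e.g. Flolan, Veletri and
epoprostenol each accumulate their own strength/persistence/durability);
setting ``collapse_aliases=True`` pools every alias onto its canonical
generic before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class LexiconError(ValueError):
    """The lexicon violates one of its structural invariants."""


#: Default ICD-9/10 codes for primary pulmonary hypertension.  ICD-10
#: "I27.2" is a family head: any I27.2x sub-code matches and pools onto it.
DEFAULT_ICD_CODES = frozenset({"416.0", "I27.0", "I27.2"})

#: Default CPT right-heart-catheterization code variants (93501 plus the
#: current combined right/left-heart catheterization family).
DEFAULT_CPT_CODES = frozenset({"93501", "93451", "93453", "93456", "93460", "93461"})

#: Canonical generic -> brand/generic aliases for the PAH-specific drugs.
DEFAULT_MEDICATIONS: dict[str, frozenset[str]] = {
    "epoprostenol": frozenset({"epoprostenol", "Flolan", "Veletri"}),
    "treprostinil": frozenset({"treprostinil", "Remodulin", "Tyvaso", "Orenitram"}),
    "iloprost": frozenset({"iloprost", "Ventavis"}),
    "bosentan": frozenset({"bosentan", "Tracleer"}),
    "ambrisentan": frozenset({"ambrisentan", "Letairis"}),
    "macitentan": frozenset({"macitentan", "Opsumit"}),
    "sildenafil": frozenset({"sildenafil", "Revatio"}),
    "tadalafil": frozenset({"tadalafil", "Adcirca"}),
    "riociguat": frozenset({"riociguat", "Adempas"}),
    "selexipag": frozenset({"selexipag", "Uptravi"}),
}

#: Therapeutic-class membership used by deployment summaries.
MEDICATION_CLASSES: dict[str, frozenset[str]] = {
    "ERA": frozenset({"bosentan", "ambrisentan", "macitentan"}),
    "GC_stimulator": frozenset({"riociguat"}),
    "PDE5_inhibitor": frozenset({"sildenafil", "tadalafil"}),
    "prostanoid": frozenset({"epoprostenol", "treprostinil", "iloprost", "selexipag"}),
}


@dataclass(frozen=True)
class Lexicon:
    """Screening lexicon: ICD codes, RHC CPT codes, medication aliases.

    Parameters
    ----------
    icd_codes
        ICD-9/10 codes for primary pulmonary hypertension.  A code ending
        in a digit acts as a family head: "I27.2" also matches "I27.21".
    cpt_codes
        Right-heart-catheterization CPT code variants; must include 93501.
    medication_names
        Map from canonical generic name to its set of brand/generic
        aliases.  Alias matching is case-insensitive; no alias may belong
        to two generics.
    collapse_aliases
        When True, medication variables are the canonical generics and all
        alias mentions pool; when False (default) each alias is its own
        screened variable.
    """

    icd_codes: frozenset[str] = DEFAULT_ICD_CODES
    cpt_codes: frozenset[str] = DEFAULT_CPT_CODES
    medication_names: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATIONS)
    )
    collapse_aliases: bool = False

    def __post_init__(self) -> None:
        if not self.icd_codes or not self.cpt_codes or not self.medication_names:
            raise LexiconError("icd_codes, cpt_codes and medication_names must be non-empty")
        if "93501" not in self.cpt_codes:
            raise LexiconError("cpt_codes must include 93501 (right heart catheterization)")
        seen: dict[str, str] = {}
        for generic, aliases in self.medication_names.items():
            if not aliases:
                raise LexiconError(f"medication {generic!r} has no aliases")
            for alias in aliases:
                key = alias.lower()
                if key in seen and seen[key] != generic:
                    raise LexiconError(
                        f"alias {alias!r} maps to both {seen[key]!r} and {generic!r}"
                    )
                seen[key] = generic
        object.__setattr__(self, "_alias_index", seen)
        # Canonical display form per lower-cased alias (first wins, sorted).
        display = {}
        for generic in self.medication_names:
            for alias in sorted(self.medication_names[generic]):
                display.setdefault(alias.lower(), alias)
        object.__setattr__(self, "_alias_display", display)

    # -- matching -----------------------------------------------------------

    def match_icd(self, code: str) -> Optional[str]:
        """Return the ICD variable a diagnosis code maps to, or None."""
        if code in self.icd_codes:
            return code
        # family-head match: I27.21 pools onto I27.2
        for head in self.icd_codes:
            if code.startswith(head) and len(code) > len(head):
                return head
        return None

    def match_cpt(self, code: str) -> Optional[str]:
        return code if code in self.cpt_codes else None

    def match_med(self, name: str) -> Optional[str]:
        """Return the medication variable a mention maps to, or None."""
        generic = self._alias_index.get(name.lower())  # type: ignore[attr-defined]
        if generic is None:
            return None
        if self.collapse_aliases:
            return generic
        return self._alias_display[name.lower()]  # type: ignore[attr-defined]

    def match(self, vocabulary: str, code: str) -> Optional[tuple[str, str]]:
        """Map an event to ``(category, variable)`` or None if unscreened.

        Categories are ``"icd"``, ``"cpt"``, ``"med"``.
        """
        if vocabulary in ("ICD9", "ICD10"):
            v = self.match_icd(code)
            return ("icd", v) if v is not None else None
        if vocabulary == "CPT":
            v = self.match_cpt(code)
            return ("cpt", v) if v is not None else None
        if vocabulary == "MED":
            v = self.match_med(code)
            return ("med", v) if v is not None else None
        return None

    # -- variable enumeration ----------------------------------------------

    def variables(self) -> list[str]:
        """Ordered list of screened variables (ICD, then CPT, then MED)."""
        meds: set[str] = set()
        if self.collapse_aliases:
            meds = set(self.medication_names)
        else:
            for aliases in self.medication_names.values():
                meds.update(aliases)
        return sorted(self.icd_codes) + sorted(self.cpt_codes) + sorted(meds)

    def generic_of(self, med_variable: str) -> Optional[str]:
        """Canonical generic for a medication variable name (None if not a med)."""
        return self._alias_index.get(med_variable.lower())  # type: ignore[attr-defined]

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "icd_codes": sorted(self.icd_codes),
            "cpt_codes": sorted(self.cpt_codes),
            "medication_names": {g: sorted(a) for g, a in sorted(self.medication_names.items())},
            "collapse_aliases": self.collapse_aliases,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        return cls(
            icd_codes=frozenset(d["icd_codes"]),
            cpt_codes=frozenset(str(c) for c in d["cpt_codes"]),
            medication_names={g: frozenset(a) for g, a in d["medication_names"].items()},
            collapse_aliases=bool(d.get("collapse_aliases", False)),
        )


def default_lexicon(collapse_aliases: bool = False) -> Lexicon:
    """The shipped default PAH screening lexicon."""
    return Lexicon(collapse_aliases=collapse_aliases)
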