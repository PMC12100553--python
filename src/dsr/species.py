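"""Species dictionary: synonym normalization and ingredient-text matching.

A dietary species richness (DSR) analysis starts from a dictionary of
edible biological species, each carrying a stable id, a scientific name,
one or more common-name synonyms and a coarse category (fish and aquatic,
fruit, vegetable, ...).  Free-text ingredient lists are matched against
the dictionary with deterministic, exact, word-boundary token matching:
longer synonyms take precedence, and tokens consumed by a longer match are
never re-matched by a shorter synonym nested inside it.  Fuzzy matching is
deliberately out of scope; irregular plurals must be listed as explicit
synonyms.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CATEGORIES",
    "SpeciesRecord",
    "SpeciesDictionary",
    "SynonymCollisionError",
    "normalize_ingredient_text",
    "compile_index",
    "match_species",
    "category_counts",
    "load_species_csv",
    "load_packaged_dictionary",
    "DEFAULT_EXCLUSION_TERMS",
]

CATEGORIES = (
    "fish_and_aquatic",
    "fruit",
    "vegetable",
    "cereal_grain",
    "legume_nut_seed",
    "animal_terrestrial",
    "fungus",
    "herb_spice",
    "other",
)

#: Default never-match terms: flavourings/extracts presented in coded or
#: unknown nomenclature.  "extract"/"flavouring" alone never name a species,
#: so listing them here only guards against a dictionary that (wrongly)
#: contains them; identifiable qualifiers such as "vanilla extract" still
#: match through the species token ("vanilla").
DEFAULT_EXCLUSION_TERMS = ("flavouring", "flavour", "extract", "essence")

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")
_NUMERIC_TOKEN_RE = re.compile(r"^\d+(\.\d+)?%?$")
_E_NUMBER_RE = re.compile(r"^e\d{3,4}[a-z]?$")


class SynonymCollisionError(ValueError):
    """Two species claim the same normalized synonym."""


def _singularize(token: str) -> str:
    """Strip regular English plural suffixes only (-s, -es, -ies)."""
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith(("oes", "ches", "shes", "sses", "xes", "zes")):
        return token[:-2]
    if len(token) > 2 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def normalize_ingredient_text(text: str) -> tuple[str, ...]:
    """Normalize raw ingredient text to a token sequence.

    Lower-cases, folds diacritics, strips punctuation and percentage /
    numeric annotations, and reduces regular plurals to singular.  The
    transform is deterministic and idempotent: normalizing the joined
    output again yields the same tokens.  Empty input yields an empty
    sequence.
    """
    if not text:
        return ()
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.lower()
    text = _PUNCT_RE.sub(" ", text)
    tokens = []
    for tok in _WS_RE.split(text):
        if not tok or _NUMERIC_TOKEN_RE.match(tok):
            continue
        tokens.append(_singularize(tok))
    return tuple(tokens)


@dataclass(frozen=True)
class SpeciesRecord:
    """One edible species with its synonyms and category."""

    species_id: str
    scientific_name: str
    common_names: tuple[str, ...]
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.species_id}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        norm = [normalize_ingredient_text(n) for n in self.common_names]
        if not any(norm):
            raise ValueError(f"{self.species_id}: no non-empty synonym after normalization")


@dataclass(frozen=True)
class OverrideRule:
    """Post-matching curation rule: force-include or force-exclude a species
    whenever ``pattern`` occurs (word-boundary) in the ingredient text."""

    pattern: str
    species_id: str
    action: str  # "include" | "exclude"


@dataclass
class SpeciesDictionary:
    """Compiled species dictionary with a normalized-synonym index.

    ``index`` maps a normalized synonym token-tuple to a species id; a
    normalized synonym mapping to two species is a load-time error.  The
    index is regenerated from ``records`` deterministically, so compiling
    twice gives identical dictionaries.
    """

    records: tuple[SpeciesRecord, ...]
    index: dict[tuple[str, ...], str] = field(default_factory=dict)
    exclusion_terms: tuple[tuple[str, ...], ...] = ()
    overrides: tuple[OverrideRule, ...] = ()
    _max_len: int = 1

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(r.species_id for r in self.records)


def compile_index(
    records: Iterable[SpeciesRecord],
    exclusion_terms: Sequence[str] = DEFAULT_EXCLUSION_TERMS,
    overrides: Sequence[OverrideRule] = (),
) -> SpeciesDictionary:
    """Build a :class:`SpeciesDictionary` from records.

    Raises :class:`SynonymCollisionError` (naming both species ids) if two
    species share a normalized synonym, and ``ValueError`` on duplicate
    species ids.
    """
    records = tuple(records)
    seen_ids: set[str] = set()
    index: dict[tuple[str, ...], str] = {}
    max_len = 1
    for rec in records:
        if rec.species_id in seen_ids:
            raise ValueError(f"duplicate species_id {rec.species_id!r}")
        seen_ids.add(rec.species_id)
        for name in rec.common_names:
            key = normalize_ingredient_text(name)
            if not key:
                continue
            prev = index.get(key)
            if prev is not None and prev != rec.species_id:
                raise SynonymCollisionError(
                    f"synonym {' '.join(key)!r} claimed by both "
                    f"{prev!r} and {rec.species_id!r}"
                )
            index[key] = rec.species_id
            max_len = max(max_len, len(key))
    excl = tuple(
        t for t in (normalize_ingredient_text(e) for e in exclusion_terms) if t
    )
    return SpeciesDictionary(
        records=records,
        index=index,
        exclusion_terms=excl,
        overrides=tuple(overrides),
        _max_len=max_len,
    )


def _subsequence_present(needle: tuple[str, ...], hay: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(hay[i : i + n] == needle for i in range(len(hay) - n + 1))


def match_species(ingredient_text: str, dictionary: SpeciesDictionary) -> set[str]:
    """Return the set of species ids whose synonyms occur in the text.

    Matching is exact on normalized tokens with word boundaries: a synonym
    matches only as a contiguous token subsequence.  Longer synonyms are
    tried first and consume their tokens, so "pineapple" never yields an
    "apple" match.  Exclusion terms never match and never consume tokens.
    The result is independent of ingredient order.  Override rules (the
    machine-readable stand-in for manual curation) are applied last.
    """
    tokens = normalize_ingredient_text(ingredient_text)
    matched: set[str] = set()
    if tokens:
        consumed = [False] * len(tokens)
        exclusions = set(dictionary.exclusion_terms)
        for length in range(min(dictionary._max_len, len(tokens)), 0, -1):
            for start in range(len(tokens) - length + 1):
                span = tokens[start : start + length]
                if any(consumed[start : start + length]):
                    continue
                if span in exclusions:
                    continue
                sid = dictionary.index.get(span)
                if sid is not None:
                    matched.add(sid)
                    for i in range(start, start + length):
                        consumed[i] = True
    for rule in dictionary.overrides:
        pat = normalize_ingredient_text(rule.pattern)
        if pat and _subsequence_present(pat, tokens):
            if rule.action == "include":
                matched.add(rule.species_id)
            elif rule.action == "exclude":
                matched.discard(rule.species_id)
    return matched


def category_counts(dictionary: SpeciesDictionary) -> dict[str, dict[str, float]]:
    """Per-category species counts and proportions (proportions sum to 1)."""
    if not dictionary.records:
        raise ValueError("empty dictionary")
    counts: dict[str, int] = {}
    for rec in dictionary.records:
        counts[rec.category] = counts.get(rec.category, 0) + 1
    total = len(dictionary.records)
    return {
        cat: {"count": n, "proportion": n / total} for cat, n in sorted(counts.items())
    }


def load_species_csv(
    path: str | Path,
    exclusion_terms: Sequence[str] = DEFAULT_EXCLUSION_TERMS,
    overrides_path: str | Path | None = None,
) -> SpeciesDictionary:
    """Load a species dictionary from CSV.

    Expected columns: species_id, scientific_name, synonyms
    (semicolon-delimited), category.  An optional override CSV has columns
    pattern, species_id, action (include|exclude).
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"species_id", "scientific_name", "synonyms", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            records.append(
                SpeciesRecord(
                    species_id=row["species_id"].strip(),
                    scientific_name=row["scientific_name"].strip(),
                    common_names=tuple(
                        s.strip() for s in row["synonyms"].split(";") if s.strip()
                    ),
                    category=row["category"].strip(),
                )
            )
    overrides: list[OverrideRule] = []
    if overrides_path is not None:
        with open(overrides_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                action = row["action"].strip().lower()
                if action not in ("include", "exclude"):
                    raise ValueError(f"override action must be include/exclude: {row}")
                overrides.append(
                    OverrideRule(row["pattern"].strip(), row["species_id"].strip(), action)
                )
    return compile_index(records, exclusion_terms=exclusion_terms, overrides=overrides)


def load_packaged_dictionary() -> SpeciesDictionary:
    """Load the packaged 269-species reference list.

    The shipped list is a curated synthetic stand-in for the species list
    used to annotate the UK nutrient databank: real edible species with
    real synonyms, built to the same size (269) and similar category mix.
    """
    ref = resources.files("dsr.data") / "species_dictionary_synthetic_269.csv"
    with resources.as_file(ref) as p:
        return load_species_csv(p)
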