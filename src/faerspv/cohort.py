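"""Primary-suspect cohort selection via drug-name/variant dictionaries.

Verbatim FAERS drug names embed strengths, formulations and co-pack text,
so matching is substring containment of a normalized variant inside the
normalized ``drugname`` or ``prod_ai`` field. The shipped default
dictionary covers palbociclib, ribociclib and abemaciclib (ingredient and
brand variants); users can supply their own YAML.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from faerspv.faers_io import CaseReport

logger = logging.getLogger(__name__)

_NON_ALNUM = re.compile(r"[^A-Z0-9]+")


class ConfigurationError(ValueError):
    pass


def normalize_name(text: str) -> str:
    """Uppercase, strip punctuation, collapse whitespace. Idempotent."""
    return _NON_ALNUM.sub(" ", text.upper()).strip()


@dataclass
class DrugDictionary:
    """Variant patterns for one drug, stored normalized."""

    drug_id: str
    ingredient_variants: list[str] = field(default_factory=list)
    brand_variants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ingredient_variants = [normalize_name(v) for v in self.ingredient_variants if v.strip()]
        self.brand_variants = [normalize_name(v) for v in self.brand_variants if v.strip()]
        if not (self.ingredient_variants or self.brand_variants):
            raise ConfigurationError(f"drug {self.drug_id!r} has no variants")

    @property
    def variants(self) -> list[str]:
        return self.ingredient_variants + self.brand_variants


def load_drug_dictionary(path: str | None = None) -> list[DrugDictionary]:
    """Load a drug dictionary from YAML; with ``path=None`` the bundled
    three-drug dictionary is used.

    YAML layout::

        palbociclib:
          ingredient: [PALBOCICLIB]
          brand: [IBRANCE]
    """
    if path is None:
        text = resources.files("faerspv.data").joinpath("drugs.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not raw:
        raise ConfigurationError("drug dictionary is empty")
    return [
        DrugDictionary(
            drug_id=drug_id,
            ingredient_variants=list(spec.get("ingredient", [])),
            brand_variants=list(spec.get("brand", [])),
        )
        for drug_id, spec in raw.items()
    ]


def match_drug(drugname: str, prod_ai: str, dictionary: list[DrugDictionary]) -> list[str]:
    """Return all drug_ids whose variants occur as substrings of the
    normalized ``drugname`` or ``prod_ai``; empty list when none match."""
    name = normalize_name(drugname)
    ai = normalize_name(prod_ai)
    hits = []
    for entry in dictionary:
        if any(v in name or v in ai for v in entry.variants):
            hits.append(entry.drug_id)
    return hits


def normalized_drugnames(case: CaseReport) -> tuple[str, ...]:
    """Sorted deduplicated normalized drug names of a report, used both by
    the cross-caseid dedup key and by diagnostics. Falls back to prod_ai
    when the verbatim name is empty."""
    names = {normalize_name(d.drugname or d.prod_ai) for d in case.drugs}
    names.discard("")
    return tuple(sorted(names))


def select_primary_suspect(
    cases: list[CaseReport], dictionary: list[DrugDictionary]
) -> dict[str, list[CaseReport]]:
    """Partition cleaned reports into per-drug subsets by primary-suspect
    (role code PS) drug rows matched against the dictionary.

    A report enters drug D's subset iff some PS drug row matches D; a report
    with PS rows matching several drugs enters every matched subset.
    """
    if not dictionary:
        raise ConfigurationError("drug dictionary has no drugs")
    subsets: dict[str, list[CaseReport]] = {d.drug_id: [] for d in dictionary}
    for case in cases:
        matched: set[str] = set()
        for drug in case.drugs:
            if drug.role_cod == "PS":
                matched.update(match_drug(drug.drugname, drug.prod_ai, dictionary))
        for drug_id in matched:
            subsets[drug_id].append(case)
    for drug_id, subset in subsets.items():
        logger.info("primary-suspect subset %s: %d reports", drug_id, len(subset))
    return subsets
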