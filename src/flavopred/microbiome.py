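"""Organism × EC-number incidence model and taxon capability tables.

A gut-community metabolic model is summarized as a matrix of strains and
the EC numbers of the enzymes their genomes encode, with phylum/family/
genus labels per strain. Predicted operators carry EC annotations from
their source reactions; candidate organisms are those carrying an enzyme
that matches at *three-digit* EC resolution — the fourth EC field encodes
the natural substrate or cofactor, and the whole premise of promiscuity
prediction is that enzymes act on non-natural substrates, so it is ignored.

Capability tables count matching strain–enzyme incidences per taxon and
reaction class, normalized by the taxon's strain count (a strain carrying
k distinct matching ECs contributes k to the numerator).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_EC_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)\.(\d+|-)$")

TAXONOMY_LEVELS = ("phylum", "family", "genus")


class ECFormatError(ValueError):
    pass


def _ec_fields(ec: str) -> tuple[str, str, str, str]:
    m = _EC_RE.match(ec.strip())
    if m is None:
        raise ECFormatError(
            f"malformed EC number {ec!r} (expected d.d.d.d or d.d.d.-)"
        )
    return m.groups()


def ec_match3(a: str, b: str) -> bool:
    """True iff the first three numeric EC fields of *a* and *b* agree.

    A wildcard ``-`` is permitted (and irrelevant) in the fourth field
    only; wildcards in the first three fields are rejected as malformed.
    """
    return _ec_fields(a)[:3] == _ec_fields(b)[:3]


@dataclass
class OrganismEnzymeMatrix:
    """Strain × EC incidence with per-strain taxonomy labels."""

    strains: list[str]
    ec_sets: dict[str, set[str]]
    taxonomy: dict[str, dict[str, str]]  # strain -> {phylum, family, genus}

    def __post_init__(self):
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain ids must be unique")
        for s in self.strains:
            for ec in self.ec_sets.get(s, ()):
                _ec_fields(ec)  # validates syntax
            if s not in self.taxonomy:
                raise ValueError(f"strain {s} has no taxonomy labels")

    def taxon_of(self, strain: str, level: str) -> str:
        if level not in TAXONOMY_LEVELS:
            raise ValueError(f"unknown taxonomy level {level!r}")
        return self.taxonomy[strain][level]

    def strains_in(self, level: str, taxon: str) -> list[str]:
        return [s for s in self.strains if self.taxon_of(s, level) == taxon]

    def taxa(self, level: str) -> list[str]:
        return sorted({self.taxon_of(s, level) for s in self.strains})

    # -- I/O --------------------------------------------------------------

    def to_tsv(self) -> str:
        rows = [
            {
                "strain": s,
                "phylum": self.taxonomy[s]["phylum"],
                "family": self.taxonomy[s]["family"],
                "genus": self.taxonomy[s]["genus"],
                "ec_numbers": ";".join(sorted(self.ec_sets.get(s, set()))),
            }
            for s in self.strains
        ]
        return pd.DataFrame(rows).to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "OrganismEnzymeMatrix":
        from io import StringIO

        df = pd.read_csv(StringIO(text), sep="\t", dtype=str).fillna("")
        strains = df["strain"].tolist()
        ec_sets = {
            row.strain: {e for e in row.ec_numbers.split(";") if e}
            for row in df.itertuples()
        }
        taxonomy = {
            row.strain: {
                "phylum": row.phylum,
                "family": row.family,
                "genus": row.genus,
            }
            for row in df.itertuples()
        }
        return cls(strains, ec_sets, taxonomy)


def organisms_for(
    op_ecs: Sequence[str], m: OrganismEnzymeMatrix
) -> list[str]:
    """Strains carrying a 3-digit EC match to any query EC; sorted, unique."""
    hits = set()
    for s in m.strains:
        for ec in m.ec_sets.get(s, ()):
            if any(ec_match3(ec, q) for q in op_ecs):
                hits.add(s)
                break
    return sorted(hits)


@dataclass
class ReactionCapabilityTable:
    """Long-format (taxon, reaction class) -> normalized matching-enzyme count."""

    level: str
    values: pd.DataFrame  # columns: taxon, reaction_class, value

    def cell(self, taxon: str, reaction_class: str) -> float:
        sel = self.values[
            (self.values.taxon == taxon)
            & (self.values.reaction_class == reaction_class)
        ]
        if sel.empty:
            raise KeyError((taxon, reaction_class))
        return float(sel.value.iloc[0])

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t", index=False)

    def to_matrix(self) -> pd.DataFrame:
        """Wide form (taxa × reaction classes) for heatmap plotting."""
        return self.values.pivot(
            index="taxon", columns="reaction_class", values="value"
        )


def capability_table(
    class_ecs: Mapping[str, Iterable[str]],
    m: OrganismEnzymeMatrix,
    level: str = "phylum",
) -> ReactionCapabilityTable:
    """Per-taxon, per-reaction-class matching-enzyme counts, strain-normalized.

    ``class_ecs`` maps each reaction class (methylation, hydroxylation,
    C-ring cleavage, ...) to the EC numbers of the operators predicted for
    it. The cell for (taxon, class) is the number of (strain, EC) pairs in
    the taxon whose EC matches the class at 3-digit resolution, divided by
    the taxon's strain count.
    """
    if level not in TAXONOMY_LEVELS:
        raise ValueError(f"unknown taxonomy level {level!r}")
    rows = []
    for taxon in m.taxa(level):
        members = m.strains_in(level, taxon)
        for rclass in sorted(class_ecs):
            queries = list(class_ecs[rclass])
            count = sum(
                1
                for s in members
                for ec in m.ec_sets.get(s, ())
                if any(ec_match3(ec, q) for q in queries)
            )
            rows.append(
                {
                    "taxon": taxon,
                    "reaction_class": rclass,
                    "value": count / len(members),
                }
            )
    return ReactionCapabilityTable(level, pd.DataFrame(rows))


def class_ec_map(operators: Iterable) -> dict[str, set[str]]:
    """Group operator EC annotations by their declared reaction class."""
    out: dict[str, set[str]] = {}
    for op in operators:
        if op.reaction_class is None:
            continue
        out.setdefault(op.reaction_class, set()).update(op.ec_numbers)
    return out
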