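"""In silico proteolysis: cleavage rules, fragments, DHt, release frequency.

A protease is modelled as a P1/P1' rule: the peptide bond after residue i
is cleaved iff residue i is in the P1 set and residue i+1 is not in the
P1' exclusion set.  From the resulting fragments two statistics follow:

* theoretical degree of hydrolysis, DHt = 100 * cleaved bonds / (N - 1);
* frequency of release A_E = (fragments exactly matching a reference
  bioactive fragment, counted with multiplicity) / N.

Release uses exact equality, not substring containment: a bioactive motif
still buried inside a longer fragment has not been released.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .proteome import CANONICAL_RESIDUES, BioactiveReference, ProteinRecord

__all__ = [
    "ProteaseRule",
    "DigestResult",
    "load_rules",
    "default_rules",
    "digest",
    "release_frequency",
    "enzyme_panel",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Named cleavage specificity: cleave after P1 unless P1' is excluded."""

    name: str
    p1_residues: frozenset
    p1prime_exclusions: frozenset = frozenset()

    def __post_init__(self) -> None:
        p1 = frozenset(str(r).upper() for r in self.p1_residues)
        excl = frozenset(str(r).upper() for r in self.p1prime_exclusions)
        if not p1:
            raise ValueError(f"rule {self.name!r}: empty P1 set")
        for s, what in ((p1, "P1"), (excl, "P1'")):
            bad = sorted(s - CANONICAL_RESIDUES)
            if bad:
                raise ValueError(
                    f"rule {self.name!r}: non-canonical {what} residue(s) {''.join(bad)!r}"
                )
        object.__setattr__(self, "p1_residues", p1)
        object.__setattr__(self, "p1prime_exclusions", excl)

    def cleaves_after(self, sequence: str, i: int) -> bool:
        """Is the bond between residues i and i+1 (0-based) cleaved?"""
        return (
            sequence[i] in self.p1_residues
            and sequence[i + 1] not in self.p1prime_exclusions
        )


@dataclass
class DigestResult:
    """Cleavage sites (1-based bond indices), fragments, and DHt of one digest."""

    protein_id: str
    enzyme: str
    sequence: str
    cleavage_sites: list[int]
    fragments: list[str] = field(init=False)
    dht_percent: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        cuts = [0] + list(self.cleavage_sites) + [n]
        self.fragments = [
            self.sequence[a:b] for a, b in zip(cuts[:-1], cuts[1:])
        ]
        self.dht_percent = 100.0 * len(self.cleavage_sites) / (n - 1)


def digest(protein: ProteinRecord, rule: ProteaseRule) -> DigestResult:
    """Apply one cleavage rule to one protein; error on single-residue chains."""
    seq = protein.sequence
    if len(seq) < 2:
        raise ValueError(
            f"record {protein.id!r}: single-residue protein has no peptide bonds; "
            "DHt is undefined"
        )
    sites = [i + 1 for i in range(len(seq) - 1) if rule.cleaves_after(seq, i)]
    return DigestResult(
        protein_id=protein.id, enzyme=rule.name, sequence=seq, cleavage_sites=sites
    )


def release_frequency(result: DigestResult, ref: BioactiveReference) -> dict[str, float]:
    """A_E per activity: exact-match released fragments (with multiplicity) / N."""
    n = len(result.sequence)
    out = {}
    for activity in ref.activities:
        frags = ref.fragments(activity)
        out[activity] = sum(1 for f in result.fragments if f in frags) / n
    return out


def enzyme_panel(
    proteins: list[ProteinRecord],
    rules: list[ProteaseRule],
    ref: BioactiveReference,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DHt and A_E for every (protein, enzyme) pair, plus per-enzyme summaries.

    Returns ``(detail, summary)`` frames.  The summary reports, per enzyme
    and activity, the across-protein mean and range of DHt and A_E, and
    also pooled variants (total cleaved bonds over total bonds; total
    released fragments over total residues) since either aggregation is
    defensible for a multi-protein substrate.
    """
    if not proteins or not rules:
        raise ValueError("enzyme_panel needs at least one protein and one rule")
    rows = []
    for rule in rules:
        for protein in proteins:
            res = digest(protein, rule)
            rel = release_frequency(res, ref)
            for activity, a_e in rel.items():
                rows.append(
                    {
                        "enzyme": rule.name,
                        "protein_id": protein.id,
                        "activity": activity,
                        "n_residues": len(protein),
                        "n_cleavages": len(res.cleavage_sites),
                        "n_released": round(a_e * len(protein)),
                        "dht_percent": res.dht_percent,
                        "release_frequency": a_e,
                    }
                )
    detail = pd.DataFrame(rows)

    def _summarize(g: pd.DataFrame) -> pd.Series:
        total_bonds = (g["n_residues"] - 1).sum()
        total_res = g["n_residues"].sum()
        return pd.Series(
            {
                "mean_dht": g["dht_percent"].mean(),
                "min_dht": g["dht_percent"].min(),
                "max_dht": g["dht_percent"].max(),
                "pooled_dht": 100.0 * g["n_cleavages"].sum() / total_bonds,
                "mean_release": g["release_frequency"].mean(),
                "min_release": g["release_frequency"].min(),
                "max_release": g["release_frequency"].max(),
                "pooled_release": g["n_released"].sum() / total_res,
            }
        )

    summary = (
        detail.groupby(["enzyme", "activity"], sort=False)
        .apply(_summarize, include_groups=False)
        .reset_index()
    )
    return detail, summary


def load_rules(path) -> list[ProteaseRule]:
    """Read a tab-separated rule table: ``enzyme<TAB>p1_set<TAB>p1prime_exclusions``."""
    rules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            name, p1, excl = (p.strip() for p in parts)
            if name.lower() == "enzyme":  # header
                continue
            rules.append(
                ProteaseRule(
                    name=name,
                    p1_residues=frozenset(p1),
                    p1prime_exclusions=frozenset() if excl in ("-", "") else frozenset(excl),
                )
            )
    if not rules:
        raise ValueError(f"{path}: no rules found")
    return rules


def default_rules() -> list[ProteaseRule]:
    """The bundled seven-enzyme rule table (simplified literature specificities)."""
    with resources.as_file(
        resources.files("acepep.data").joinpath("protease_rules.tsv")
    ) as p:
        return load_rules(p)
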