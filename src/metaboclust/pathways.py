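"""Joint gene + metabolite pathway over-representation.

Significant genes (e.g. SAM adjusted p < 0.05) and significant metabolites
are pooled into one significant list over a combined universe (gene and
metabolite namespaces are disjoint); each pathway is tested for
over-representation of its members among the significant entities with a
one-sided hypergeometric upper tail.  Pathways with p <= 0.05 are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class Pathway:
    name: str
    genes: tuple[str, ...]
    metabolites: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.name}: duplicate gene members")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError(f"{self.name}: duplicate metabolite members")
        if not (self.genes or self.metabolites):
            raise ValueError(f"{self.name}: pathway has no members")

    @property
    def members(self) -> frozenset:
        return frozenset(self.genes) | frozenset(self.metabolites)


def pathway_from_dict(d: dict) -> Pathway:
    return Pathway(
        name=d["name"],
        genes=tuple(d.get("genes", ())),
        metabolites=tuple(d.get("metabolites", ())),
    )


def joint_enrichment(
    sig_genes,
    sig_metabolites,
    universe_genes,
    universe_metabolites,
    pathways: list[Pathway] | list[dict],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway.

    Returns a frame sorted by p with columns size (pathway members in the
    combined universe), hits (significant members), p, significant.
    Pathways with no member in the universe are skipped with a warning.
    """
    pathways = [p if isinstance(p, Pathway) else pathway_from_dict(p) for p in pathways]
    universe = set(universe_genes) | set(universe_metabolites)
    sig = set(sig_genes) | set(sig_metabolites)
    missing = sig - universe
    if missing:
        raise ValueError(
            f"significant entities missing from the universe: {sorted(missing)[:5]}"
        )
    rows = []
    for pw in pathways:
        members = pw.members & universe
        if not members:
            warnings.warn(f"pathway {pw.name!r} has no member in the universe; skipped")
            continue
        hits = len(members & sig)
        # P(X >= hits), X ~ Hypergeom(|U|, |members|, |sig|)
        p = float(hypergeom.sf(hits - 1, len(universe), len(members), len(sig)))
        rows.append((pw.name, len(members), hits, p))
    out = pd.DataFrame(rows, columns=["pathway", "size", "hits", "p"]).set_index("pathway")
    out["significant"] = out["p"] <= alpha
    return out.sort_values(["p", "size"], kind="stable")


__all__ = ["Pathway", "pathway_from_dict", "joint_enrichment"]
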