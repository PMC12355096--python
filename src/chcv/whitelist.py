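"""The CHIP variant whitelist.

A whitelist has two record kinds: exact protein-change ``site`` entries and
gene-level ``rule`` entries matching consequence classes (e.g. any
frameshift/nonsense/splice variant in a loss-of-function gene).  The packaged
list is an editable, documented stand-in assembled from well-known CHIP
hotspots and loss-of-function gene rules; the three catalytic TET2 sites are
exempt from the germline binomial test, and three recurrent technical
artifacts are flagged for downstream removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import FrozenSet, Set, Tuple

import pandas as pd

from .config import PANEL_GENES

#: sites exempt from the binomial somatic test (likely true CHIP despite
#: germline-like VAF)
BINOMIAL_EXEMPT: FrozenSet[Tuple[str, str]] = frozenset({
    ("TET2", "p.H1904R"), ("TET2", "p.I1873T"), ("TET2", "p.T1884A"),
})

#: recurrent technical artifacts removed after whitelist matching; the
#: ASXL1 frameshift is a genuine hotspot at larger clone sizes and is only
#: removed when VAF < 0.1 (configurable, see ChipCaller)
ARTIFACT_UNCONDITIONAL: FrozenSet[Tuple[str, str]] = frozenset({
    ("TP53", "p.P72R"), ("ASXL1", "p.P815L"),
})
ARTIFACT_VAF_CONDITIONAL: FrozenSet[Tuple[str, str]] = frozenset({
    ("ASXL1", "p.G646Wfs*12"),
})


@dataclass
class Whitelist:
    """Prespecified CHIP variant list with site entries and gene rules."""

    sites: Set[Tuple[str, str]] = field(default_factory=set)
    #: gene -> set of consequence classes admitted by rule
    rules: dict = field(default_factory=dict)
    binomial_exempt: FrozenSet[Tuple[str, str]] = BINOMIAL_EXEMPT
    artifacts_unconditional: FrozenSet[Tuple[str, str]] = ARTIFACT_UNCONDITIONAL
    artifacts_vaf_conditional: FrozenSet[Tuple[str, str]] = ARTIFACT_VAF_CONDITIONAL

    def __post_init__(self) -> None:
        overlap = set(self.binomial_exempt) & (
            set(self.artifacts_unconditional) | set(self.artifacts_vaf_conditional))
        if overlap:
            raise ValueError(f"binomial exemptions overlap artifact list: {overlap}")

    def matches(self, gene: str, hgvs_p: str, consequence: str) -> bool:
        """True iff the variant matches a site entry or a gene rule.

        Raises ``ValueError`` for genes outside the 11-gene panel.
        """
        if gene not in PANEL_GENES:
            raise ValueError(
                f"gene {gene!r} is not in the 11-gene CHIP panel {PANEL_GENES}")
        if (gene, hgvs_p) in self.sites:
            return True
        return consequence in self.rules.get(gene, ())

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "Whitelist":
        df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
        required = {"kind", "gene", "hgvs_p", "consequences"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"whitelist TSV missing columns: {sorted(missing)}")
        sites: Set[Tuple[str, str]] = set()
        rules: dict = {}
        for row in df.itertuples(index=False):
            if row.kind == "site":
                sites.add((row.gene, row.hgvs_p))
            elif row.kind == "rule":
                rules.setdefault(row.gene, set()).update(
                    c.strip() for c in str(row.consequences).split(","))
            else:
                raise ValueError(f"unknown whitelist record kind {row.kind!r}")
        return cls(sites=sites, rules=rules)


def load_default_whitelist() -> Whitelist:
    """Load the whitelist TSV packaged with chcv."""
    ref = resources.files("chcv").joinpath("data/chip_whitelist.tsv")
    with resources.as_file(ref) as path:
        return Whitelist.from_tsv(path)
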