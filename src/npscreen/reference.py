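"""Bundled reference tables for the presenilin-dKO neuropsychiatric screen.

These are the published snapshot values the worked examples and the
``paper_like`` synthetic preset are parameterized with: per-term gene-pool
sizes from the 2017-09-19 GO annotation snapshot, per-disorder pool unions
with overlap counts, reported DEG counts, and the cross-age fold-change table
for the genes significant at both ages.  They are *inputs* to the package —
fixture parameters and example data — not quantities it recomputes from live
annotation databases.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Per-term gene-set sizes (2017-09-19 annotation snapshot).
TERM_SIZES: dict[str, int] = {
    "GO:0051568": 32,   # Histone H3-K4 methylation (BIP and SCZ)
    "GO:0007129": 23,   # (Chromosomal) synapsis
    "GO:0090066": 54,   # Regulation of anatomical structure size
    "GO:0070192": 362,  # Chromosome organization involved in meiosis
    "GO:0014069": 205,  # Postsynaptic density
    "GO:0045211": 207,  # Postsynaptic membrane
    "GO:0043197": 116,  # Dendritic spine
    "GO:0033267": 192,  # Axon part
    "GO:0008601": 8,    # Protein phosphatase type 2A regulator activity
    "GO:0034330": 137,  # Cell junction organization
    "GO:0043297": 122,  # Apical junction assembly
    "GO:0045216": 67,   # Cell-cell junction organization
    "GO:0031056": 135,  # Regulation of histone modification
}

#: Deduplicated pool-union sizes per disorder.
POOL_SIZES: dict[str, int] = {"BIP": 448, "SCZ": 556, "MDD": 335}

#: Redundant memberships (sum of term sizes minus union size) per disorder.
POOL_OVERLAPS: dict[str, int] = {"BIP": 23, "SCZ": 196, "MDD": 134}

#: Reported number of pool genes called differentially expressed, per disorder
#: (union over both regions and both ages), and the array-wide DEG total.
REPORTED_DEG_COUNTS: dict[str, int] = {"BIP": 93, "SCZ": 111, "MDD": 69}
REPORTED_TOTAL_DEGS: int = 2261


@dataclass(frozen=True)
class CrossAgeEntry:
    """One gene's fold changes and significance calls in one region.

    ``fc`` holds the KO/WT linear-scale fold change at 7 and 18 months;
    ``significant`` the corresponding DEG calls (p < 0.05 and symmetric fold
    change > 1.3).
    """

    gene: str
    disorder: str
    region: str
    fc: tuple[float, float]
    significant: tuple[bool, bool]


#: Cross-age fold-change table for the genes significant at both ages in at
#: least one region ("common genes"), with per-region significance patterns.
CROSS_AGE_TABLE: tuple[CrossAgeEntry, ...] = (
    # SCZ
    CrossAgeEntry("Hist1h1c", "SCZ", "cortex", (1.802, 1.688), (True, True)),
    CrossAgeEntry("Hist1h1c", "SCZ", "hippocampus", (1.536, 1.175), (False, False)),
    CrossAgeEntry("Pcdhb16", "SCZ", "cortex", (0.692, 0.740), (True, True)),
    CrossAgeEntry("Pcdhb16", "SCZ", "hippocampus", (1.034, 1.135), (False, False)),
    CrossAgeEntry("Arc", "SCZ", "cortex", (1.512, 0.422), (False, False)),
    CrossAgeEntry("Arc", "SCZ", "hippocampus", (1.652, 0.615), (True, True)),
    CrossAgeEntry("Cnn3", "SCZ", "cortex", (1.255, 1.877), (False, False)),
    CrossAgeEntry("Cnn3", "SCZ", "hippocampus", (1.380, 1.207), (True, True)),
    CrossAgeEntry("Stx3", "SCZ", "cortex", (1.062, 0.869), (False, False)),
    CrossAgeEntry("Stx3", "SCZ", "hippocampus", (1.582, 1.376), (True, True)),
    # BIP
    CrossAgeEntry("Hist1h1c", "BIP", "cortex", (1.802, 1.688), (True, True)),
    CrossAgeEntry("Hist1h1c", "BIP", "hippocampus", (1.536, 1.175), (False, False)),
    CrossAgeEntry("Arpc1b", "BIP", "cortex", (1.887, 1.661), (False, False)),
    CrossAgeEntry("Arpc1b", "BIP", "hippocampus", (1.639, 1.870), (True, True)),
    # MDD
    CrossAgeEntry("Paxbp1", "MDD", "cortex", (1.356, 0.767), (True, True)),
    CrossAgeEntry("Paxbp1", "MDD", "hippocampus", (1.337, 1.020), (False, False)),
    CrossAgeEntry("Sorbs1", "MDD", "cortex", (1.465, 1.781), (True, True)),
    CrossAgeEntry("Sorbs1", "MDD", "hippocampus", (1.161, 1.368), (False, False)),
    CrossAgeEntry("Kdm2a", "MDD", "cortex", (2.237, 2.511), (True, True)),
    CrossAgeEntry("Kdm2a", "MDD", "hippocampus", (2.229, 1.755), (False, False)),
)

#: Home GO term used when embedding each named gene into the synthetic pools.
NAMED_GENE_TERMS: dict[str, str] = {
    "Hist1h1c": "GO:0051568",  # histone H3-K4 methylation (shared BIP/SCZ)
    "Pcdhb16": "GO:0045211",   # postsynaptic membrane
    "Arc": "GO:0014069",       # postsynaptic density
    "Cnn3": "GO:0043197",      # dendritic spine
    "Stx3": "GO:0033267",      # axon part
    "Arpc1b": "GO:0090066",    # regulation of anatomical structure size
    "Paxbp1": "GO:0034330",    # cell junction organization
    "Sorbs1": "GO:0045216",    # cell-cell junction organization
    "Kdm2a": "GO:0031056",     # regulation of histone modification
}
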