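"""Allelic diversity statistics per variety / breeder / ploidy class.

Quantities follow the standard population-genetic definitions: expected
heterozygosity (gene diversity) He = 1 - sum(p_i^2); effective number of
alleles n_e = 1 / sum(p_i^2), so that n_e = 1 / (1 - He); allelic richness
by hypergeometric rarefaction to a standard number of gene copies.

Allele frequencies come in two flavours matching the two scoring modes:

* dominant — p_i is the number of plants *carrying* allele i divided by the
  summed carrier counts over all alleles at the locus (so the vector sums
  to 1).  This is the only frequency notion available when dosage is
  unrecorded and ploidy is mixed.
* codominant — p_i is the allele-copy frequency among scored diploid
  genotypes (copies / 2n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PhenotypeMatrix
from .scoring import CodominantGenotype, to_allelic_phenotype

__all__ = [
    "FrequencyTable",
    "allele_frequencies",
    "codominant_frequencies",
    "effective_num_alleles",
    "expected_heterozygosity",
    "classify_common_rare",
    "allelic_richness",
    "summarize_variety",
    "summarize_panel",
]

GROUPINGS = ("variety", "breeder", "ploidy", "panel")


@dataclass
class FrequencyTable:
    """Per-(group, locus) allele frequency vectors and sample sizes.

    ``freqs[(group, locus)]`` is a Series indexed by allele label summing
    to 1 (when any allele was observed); ``n[(group, locus)]`` is the
    number of plants contributing (dominant mode) or plants scored
    (codominant mode).  A (group, locus) with no scored plants is absent.
    """

    mode: str
    grouping: str
    freqs: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)

    def vector(self, group, locus) -> np.ndarray:
        return self.freqs[(group, locus)].to_numpy()

    def groups(self) -> list:
        return sorted({g for g, _ in self.freqs}, key=str)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, loc, allele, p, self.n[(g, loc)])
            for (g, loc), s in self.freqs.items()
            for allele, p in s.items()
        ]
        return pd.DataFrame(rows, columns=["group", "locus", "allele", "freq", "n"])


def _group_labels(meta: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "panel":
        return pd.Series("panel", index=meta.index)
    if grouping not in ("variety", "breeder", "ploidy"):
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    return meta[grouping]


def allele_frequencies(matrix: PhenotypeMatrix, grouping: str = "variety") -> FrequencyTable:
    """Dominant-mode allele frequencies from a presence/absence matrix.

    p_i = carriers of allele i / summed carriers over the locus' alleles,
    within each group.  Loci where a group has no scored plant are marked
    unavailable (omitted from the table).
    """
    labels = _group_labels(matrix.meta, grouping)
    table = FrequencyTable(mode="dominant", grouping=grouping)
    for loc in matrix.locus_names:
        block = matrix.data[loc]
        scored = ~matrix.missing[loc]
        for g, idx in labels.groupby(labels).groups.items():
            sub = block.loc[idx]
            ok = scored.loc[idx]
            carriers = sub[ok].sum(axis=0).astype(float)
            total = carriers.sum()
            if total == 0:
                continue  # all plants missing here: locus unavailable for group
            table.freqs[(g, loc)] = carriers / total
            table.n[(g, loc)] = int(ok.sum())
    return table


def codominant_frequencies(
    genotypes: list[CodominantGenotype], grouping: str = "variety", breeders: dict | None = None
) -> FrequencyTable:
    """Codominant-mode allele-copy frequencies: p_i = copies / (2 x scored plants)."""
    table = FrequencyTable(mode="codominant", grouping=grouping)
    counts: dict = {}
    nn: dict = {}
    for gt in genotypes:
        if grouping == "variety":
            g = gt.variety
        elif grouping == "breeder":
            g = gt.breeder
        elif grouping == "panel":
            g = "panel"
        else:
            raise ValueError(f"grouping must be variety/breeder/panel for codominant data")
        for loc, pair in gt.genotypes.items():
            if pair is None:
                continue
            c = counts.setdefault((g, loc), {})
            for a in pair:
                c[a] = c.get(a, 0) + 1
            nn[(g, loc)] = nn.get((g, loc), 0) + 1
    for key, c in counts.items():
        s = pd.Series(c, dtype=float).sort_index()
        table.freqs[key] = s / s.sum()
        table.n[key] = nn[key]
    return table


def effective_num_alleles(p) -> float:
    """Effective number of alleles n_e = 1 / sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    return 1.0 / float(np.sum(p**2))


def expected_heterozygosity(p, n: int | None = None, corrected: bool = False) -> float:
    """Gene diversity He = 1 - sum(p_i^2); optional 2n/(2n-1) correction."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    he = 1.0 - float(np.sum(p**2))
    if corrected:
        if n is None or n < 2:
            raise ValueError("corrected He needs n >= 2 plants")
        he *= (2 * n) / (2 * n - 1)
    return he


def classify_common_rare(
    matrix: PhenotypeMatrix, grouping: str = "variety", threshold: float = 0.10
) -> pd.DataFrame:
    """Split observed alleles into common vs rare per (group, locus).

    An allele is *rare* within a group iff it is carried by fewer than
    ``threshold`` of the group's plants scored at that locus; alleles not
    observed in the group do not count.  Returns a DataFrame indexed by
    (group, locus) with columns allele_count / common_count / rare_count.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0,1)")
    labels = _group_labels(matrix.meta, grouping)
    rows = []
    for loc in matrix.locus_names:
        block = matrix.data[loc]
        scored = ~matrix.missing[loc]
        for g, idx in labels.groupby(labels).groups.items():
            ok = scored.loc[idx]
            n_scored = int(ok.sum())
            if n_scored == 0:
                continue
            carriers = block.loc[idx][ok].sum(axis=0)
            observed = carriers[carriers > 0]
            frac = observed / n_scored
            rare = int((frac < threshold).sum())
            rows.append((g, loc, len(observed), len(observed) - rare, rare))
    return pd.DataFrame(
        rows, columns=["group", "locus", "allele_count", "common_count", "rare_count"]
    ).set_index(["group", "locus"])


def allelic_richness(counts, g: int) -> float:
    """Rarefied allele number: E[# alleles among g gene copies drawn without replacement].

    Ar(g) = sum_i [1 - C(N - N_i, g) / C(N, g)] where N_i are per-allele
    copy counts and N their total.
    """
    counts = [int(c) for c in counts if c > 0]
    N = sum(counts)
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds total copies N={N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - Ni, g) / denom for Ni in counts))


def summarize_variety(
    panel: GenotypePanel,
    variety: str,
    rare_threshold: float = 0.10,
    matrix: PhenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Per-locus allele counts and common/rare split for one variety.

    Returns a DataFrame indexed by locus with columns allele_count,
    common_count, rare_count, n_e, He; the ``total_alleles`` attribute of
    the frame (``df.attrs``) carries the row sum of allele_count.
    """
    if variety not in panel.varieties:
        raise KeyError(f"variety {variety!r} not in panel")
    matrix = matrix if matrix is not None else to_allelic_phenotype(panel)
    keep = matrix.meta["variety"] == variety
    sub = PhenotypeMatrix(matrix.data[keep], matrix.missing[keep], matrix.meta[keep])
    cr = classify_common_rare(sub, grouping="variety", threshold=rare_threshold)
    cr = cr.loc[variety] if variety in cr.index.get_level_values(0) else cr
    freqs = allele_frequencies(sub, grouping="variety")
    rows = []
    for loc in sub.locus_names:
        if (variety, loc) not in freqs.freqs:
            rows.append((loc, 0, 0, 0, np.nan, np.nan))
            continue
        p = freqs.vector(variety, loc)
        ac = int(cr.loc[loc, "allele_count"])
        rows.append(
            (
                loc,
                ac,
                int(cr.loc[loc, "common_count"]),
                int(cr.loc[loc, "rare_count"]),
                effective_num_alleles(p),
                expected_heterozygosity(p),
            )
        )
    df = pd.DataFrame(
        rows, columns=["locus", "allele_count", "common_count", "rare_count", "n_e", "He"]
    ).set_index("locus")
    df.attrs["total_alleles"] = int(df["allele_count"].sum())
    return df


def summarize_panel(panel: GenotypePanel, rare_threshold: float = 0.10) -> pd.DataFrame:
    """Variety x locus allele-count table plus per-variety totals.

    Shaped like a variety-characterisation report: one row per variety with
    per-locus allele counts and a ``total_alleles`` column, plus a final
    ``__panel__`` row holding panel-wide per-locus allele counts and their
    grand total.
    """
    matrix = to_allelic_phenotype(panel)
    rows = {}
    for variety in panel.varieties:
        per = summarize_variety(panel, variety, rare_threshold, matrix=matrix)
        rows[variety] = per["allele_count"]
    df = pd.DataFrame(rows).T
    df["total_alleles"] = df.sum(axis=1)
    panel_counts = {
        loc: int((matrix.data[loc].sum(axis=0) > 0).sum()) for loc in matrix.locus_names
    }
    total = sum(panel_counts.values())
    df.loc["__panel__"] = pd.Series({**panel_counts, "total_alleles": total})
    return df.astype(int)
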