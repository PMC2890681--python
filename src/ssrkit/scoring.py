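"""Dominant and codominant scoring of microsatellite calls.

Dominant scoring records only the *allelic phenotype*: which alleles are
present in a plant at a locus, with dosage discarded (AAB and ABB both
become AB).  Codominant scoring, valid for diploid plants only, interprets
a one-allele call as an apparent homozygote (x, x) and a two-allele call as
a heterozygote (x, y), assuming no null alleles.  Plants from declared
diploid varieties showing three or more distinct alleles at a locus are
ploidy anomalies — typically triploids sired by stray tetraploid pollen —
and are flagged rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PhenotypeMatrix

__all__ = [
    "CodominantGenotype",
    "PloidyAnomalyReport",
    "to_allelic_phenotype",
    "detect_ploidy_anomalies",
    "to_codominant",
    "anomaly_counts_by_variety",
]


@dataclass(frozen=True)
class CodominantGenotype:
    """Diploid genotype of one plant: locus -> (x, y) label pair or None.

    Apparent homozygotes are (x, x); loci where the plant showed >= 3
    distinct alleles are set to None and listed in ``anomalous_loci``.
    """

    plant_id: str
    variety: str
    breeder: str
    genotypes: dict
    anomalous_loci: tuple = ()


@dataclass(frozen=True)
class PloidyAnomalyReport:
    """Ploidy-consistency screen of one declared-diploid plant."""

    plant_id: str
    variety: str
    loci_with_excess: tuple  # ((locus, observed allele count), ...)
    classification: str  # "consistent" | "suspected_triploid"

    def __post_init__(self):
        if (self.classification == "suspected_triploid") != bool(self.loci_with_excess):
            raise ValueError("loci_with_excess must be nonempty iff suspected_triploid")


def to_allelic_phenotype(panel: GenotypePanel) -> PhenotypeMatrix:
    """Score a panel as a plants x (locus, allele) presence/absence matrix.

    One row per plant; for each non-missing locus the columns of the
    present alleles are 1 and the rest 0; a dropout sets the missing mask
    and leaves the locus columns at 0.
    """
    cols = [(l.name, a) for l in panel.loci for a in l.alleles]
    col_idx = {c: i for i, c in enumerate(cols)}
    n = len(panel.plants)
    data = np.zeros((n, len(cols)), dtype=np.uint8)
    miss = np.zeros((n, len(panel.loci)), dtype=bool)
    ids, meta_rows = [], []
    for i, p in enumerate(panel.plants):
        ids.append(p.plant_id)
        meta_rows.append((p.variety, p.breeder, p.declared_ploidy))
        for j, loc in enumerate(panel.loci):
            call = p.calls.get(loc.name)
            if call is None:
                miss[i, j] = True
            else:
                for a in call:
                    data[i, col_idx[(loc.name, a)]] = 1
    df = pd.DataFrame(
        data, index=pd.Index(ids, name="plant_id"), columns=pd.MultiIndex.from_tuples(cols)
    )
    missing = pd.DataFrame(miss, index=df.index, columns=panel.locus_names)
    meta = pd.DataFrame(
        meta_rows, index=df.index, columns=["variety", "breeder", "ploidy"]
    )
    return PhenotypeMatrix(df, missing, meta)


def detect_ploidy_anomalies(panel: GenotypePanel) -> list[PloidyAnomalyReport]:
    """Screen declared-diploid plants for loci with >= 3 distinct alleles.

    Only plants of declared-diploid varieties are classified; a plant with
    three or more distinct alleles at one or more loci is
    ``suspected_triploid``.
    """
    reports = []
    for p in panel.plants:
        if p.declared_ploidy != 2:
            continue
        excess = tuple(
            (loc, len(call))
            for loc, call in ((l.name, p.calls.get(l.name)) for l in panel.loci)
            if call is not None and len(call) >= 3
        )
        reports.append(
            PloidyAnomalyReport(
                p.plant_id,
                p.variety,
                excess,
                "suspected_triploid" if excess else "consistent",
            )
        )
    return reports


def anomaly_counts_by_variety(reports: list[PloidyAnomalyReport]) -> pd.Series:
    """Suspected-triploid counts per declared-diploid variety."""
    counts: dict[str, int] = {}
    for r in reports:
        counts.setdefault(r.variety, 0)
        if r.classification == "suspected_triploid":
            counts[r.variety] += 1
    return pd.Series(counts, name="suspected_triploid").sort_index()


def to_codominant(
    panel: GenotypePanel, scope: str = "diploid_varieties"
) -> list[CodominantGenotype]:
    """Derive codominant diploid genotypes from call sets.

    One observed allele -> (x, x); two -> (x, y); three or more -> the
    locus is masked for that plant and recorded in ``anomalous_loci``
    (consistent with :func:`detect_ploidy_anomalies`).  Null alleles are
    assumed absent, so apparent homozygotes are taken at face value.
    """
    if scope != "diploid_varieties":
        raise ValueError(f"unsupported scope {scope!r}")
    out = []
    for p in panel.plants:
        if p.declared_ploidy != 2:
            continue
        gts: dict = {}
        anomalous = []
        for loc in panel.loci:
            call = p.calls.get(loc.name)
            if call is None:
                gts[loc.name] = None
            elif len(call) == 1:
                (a,) = call
                gts[loc.name] = (a, a)
            elif len(call) == 2:
                x, y = sorted(call)
                gts[loc.name] = (x, y)
            else:
                gts[loc.name] = None
                anomalous.append(loc.name)
        out.append(
            CodominantGenotype(p.plant_id, p.variety, p.breeder, gts, tuple(anomalous))
        )
    return out
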