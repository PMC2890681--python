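"""Hierarchical F-statistics for dominant and codominant microsatellite scores.

The estimators are the gene-diversity family: per locus,

* ``Ho`` — mean within-group observed heterozygote fraction (codominant
  diploid data only),
* ``Hs`` — mean within-group gene diversity 1 - sum(p_i^2),
* ``Ht`` — total gene diversity 1 - sum(pbar_i^2) on the unweighted mean
  of group frequency vectors,

from which Fis = 1 - Ho/Hs, Fst = 1 - Hs/Ht, Fit = 1 - Ho/Ht, linked by
(1 - Fit) = (1 - Fis)(1 - Fst).  In dominant mode the frequencies are
carrier-based allelic-phenotype frequencies, which supports plants of mixed
ploidy in one run, and only Fst is defined.  Multilocus coefficients
combine loci as ratios of summed numerators and denominators; uncertainty
comes from a delete-one-locus jackknife, and significance of Fst from
permutation of whole plants among groups.

The user-facing surface is :class:`FStatisticsModel` (build from a panel,
choose scoring mode and grouping) whose :meth:`~FStatisticsModel.fit`
returns a :class:`FStatResults` carrying per-locus and multilocus
estimates, jackknife standard errors, permutation p-values, and a
``summary()`` table.  Nei & Chesser small-sample corrected estimators and
Weir & Cockerham's theta are available as options; uncorrected
gene-diversity estimators are the default and are the ones that satisfy
the exact algebraic identities above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PhenotypeMatrix
from .scoring import CodominantGenotype, detect_ploidy_anomalies, to_allelic_phenotype, to_codominant

__all__ = [
    "FStatisticsModel",
    "FStatResults",
    "PermutationScheme",
    "ScoringComparison",
    "f_coefficients",
    "gene_diversities_codominant",
    "fst_dominant",
    "multilocus_jackknife",
    "permutation_test_fst",
    "weir_cockerham_theta",
    "compare_scoring_modes",
]


@dataclass(frozen=True)
class PermutationScheme:
    """Whole-plant permutation among groups, preserving group sizes."""

    n_permutations: int = 999
    seed: int | None = None
    unit: str = "plant"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.unit != "plant":
            raise ValueError("only whole-plant permutation is supported")


# ---------------------------------------------------------------------------
# numeric cores
# ---------------------------------------------------------------------------


class _DominantData:
    """Presence matrix with per-locus column slices; missing = all-zero block."""

    def __init__(self, matrix: PhenotypeMatrix):
        self.X = matrix.data.to_numpy(dtype=float)
        self.loci = list(matrix.locus_names)
        self.slices = []
        cols = matrix.data.columns.get_level_values(0)
        start = 0
        for loc in self.loci:
            width = int((cols == loc).sum())
            self.slices.append(slice(start, start + width))
            start += width
        self.n_plants = self.X.shape[0]


def _one_hot(codes: np.ndarray, n_groups: int) -> np.ndarray:
    G = np.zeros((n_groups, codes.size))
    G[codes, np.arange(codes.size)] = 1.0
    return G


def _dominant_hs_ht(dd: _DominantData, codes: np.ndarray, n_groups: int):
    """Per-locus (Hs, Ht) from carrier frequencies; NaN where undefined."""
    G = _one_hot(codes, n_groups)
    C = G @ dd.X
    L = len(dd.loci)
    Hs = np.full(L, np.nan)
    Ht = np.full(L, np.nan)
    for l, sl in enumerate(dd.slices):
        sub = C[:, sl]
        tot = sub.sum(axis=1)
        valid = tot > 0
        if valid.sum() == 0:
            continue
        p = sub[valid] / tot[valid, None]
        Hs[l] = float(np.mean(1.0 - np.sum(p**2, axis=1)))
        pbar = p.mean(axis=0)
        Ht[l] = 1.0 - float(np.sum(pbar**2))
    return Hs, Ht


class _CodominantData:
    """Per-locus copy-count matrices for fast group aggregation.

    For locus l: ``cnt[l]`` is plants x alleles with entries 0/1/2,
    ``valid[l]`` flags scored plants, ``het[l]`` flags heterozygotes.
    """

    def __init__(self, genotypes: list[CodominantGenotype], loci: list[str]):
        self.loci = list(loci)
        self.plant_ids = [g.plant_id for g in genotypes]
        self.n_plants = len(genotypes)
        self.alleles: list[list] = []
        self.cnt: list[np.ndarray] = []
        self.valid: list[np.ndarray] = []
        self.het: list[np.ndarray] = []
        for loc in self.loci:
            labels = sorted({a for g in genotypes for pair in [g.genotypes.get(loc)] if pair for a in pair})
            idx = {a: i for i, a in enumerate(labels)}
            cnt = np.zeros((self.n_plants, max(len(labels), 1)))
            valid = np.zeros(self.n_plants)
            het = np.zeros(self.n_plants)
            for i, g in enumerate(genotypes):
                pair = g.genotypes.get(loc)
                if pair is None:
                    continue
                valid[i] = 1.0
                x, y = pair
                cnt[i, idx[x]] += 1
                cnt[i, idx[y]] += 1
                if x != y:
                    het[i] = 1.0
            self.alleles.append(labels)
            self.cnt.append(cnt)
            self.valid.append(valid)
            self.het.append(het)


def _codominant_components(
    cd: _CodominantData, codes: np.ndarray, n_groups: int, corrected: bool = False
):
    """Per-locus (Ho, Hs, Ht); optional Nei & Chesser small-sample correction."""
    G = _one_hot(codes, n_groups)
    L = len(cd.loci)
    Ho = np.full(L, np.nan)
    Hs = np.full(L, np.nan)
    Ht = np.full(L, np.nan)
    for l in range(L):
        n_g = G @ cd.valid[l]
        keep = n_g >= (2 if corrected else 1)
        s = int(keep.sum())
        if s == 0:
            continue
        copies = (G @ cd.cnt[l])[keep]
        het_g = (G @ cd.het[l])[keep]
        n_g = n_g[keep]
        p = copies / (2.0 * n_g[:, None])
        ho_g = het_g / n_g
        ho = float(ho_g.mean())
        hs_raw = float(np.mean(1.0 - np.sum(p**2, axis=1)))
        pbar = p.mean(axis=0)
        ht_raw = 1.0 - float(np.sum(pbar**2))
        if corrected:
            n_tilde = s / np.sum(1.0 / n_g)  # harmonic mean group size
            hs = n_tilde / (n_tilde - 1.0) * (hs_raw - ho / (2.0 * n_tilde))
            ht = ht_raw + hs / (n_tilde * s) - ho / (2.0 * n_tilde * s)
        else:
            hs, ht = hs_raw, ht_raw
        Ho[l], Hs[l], Ht[l] = ho, hs, ht
    return Ho, Hs, Ht


# ---------------------------------------------------------------------------
# public estimator functions
# ---------------------------------------------------------------------------


def f_coefficients(Ho, Hs, Ht):
    """(Fis, Fst, Fit) from gene diversities; NaN where a denominator is 0.

    Works elementwise on scalars or arrays and satisfies
    (1 - Fit) = (1 - Fis)(1 - Fst) wherever all three are defined.
    """
    Ho = np.asarray(Ho, dtype=float)
    Hs = np.asarray(Hs, dtype=float)
    Ht = np.asarray(Ht, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(Hs > 0, 1.0 - Ho / Hs, np.nan)
        fst = np.where(Ht > 0, 1.0 - Hs / Ht, np.nan)
        fit = np.where(Ht > 0, 1.0 - Ho / Ht, np.nan)
    if fis.ndim == 0:
        return float(fis), float(fst), float(fit)
    return fis, fst, fit


def _groups_of(genotypes: list[CodominantGenotype], grouping: str) -> list:
    if grouping == "variety":
        return [g.variety for g in genotypes]
    if grouping == "breeder":
        return [g.breeder for g in genotypes]
    raise ValueError("codominant grouping must be 'variety' or 'breeder'")


def gene_diversities_codominant(
    genotypes: list[CodominantGenotype],
    grouping: str = "variety",
    loci: list[str] | None = None,
    corrected: bool = False,
) -> pd.DataFrame:
    """Per-locus Ho / Hs / Ht from codominantly scored diploid genotypes."""
    if loci is None:
        loci = sorted({loc for g in genotypes for loc in g.genotypes})
    labels = pd.Categorical(_groups_of(genotypes, grouping))
    if len(labels.categories) < 2:
        raise ValueError("need >= 2 groups")
    cd = _CodominantData(genotypes, loci)
    Ho, Hs, Ht = _codominant_components(cd, np.asarray(labels.codes), len(labels.categories), corrected)
    return pd.DataFrame({"Ho": Ho, "Hs": Hs, "Ht": Ht}, index=pd.Index(loci, name="locus"))


def fst_dominant(matrix: PhenotypeMatrix, grouping: str = "variety") -> pd.DataFrame:
    """Per-locus Hs / Ht / Fst from dominant carrier frequencies (mixed ploidy ok)."""
    from .diversity import _group_labels

    labels = pd.Categorical(_group_labels(matrix.meta, grouping))
    if len(labels.categories) < 2:
        raise ValueError("need >= 2 groups")
    dd = _DominantData(matrix)
    Hs, Ht = _dominant_hs_ht(dd, np.asarray(labels.codes), len(labels.categories))
    _, fst, _ = f_coefficients(np.zeros_like(Hs), Hs, Ht)
    return pd.DataFrame(
        {"Hs": Hs, "Ht": Ht, "Fst": fst}, index=pd.Index(dd.loci, name="locus")
    )


_COEFF_PARTS = {"fis": ("Ho", "Hs"), "fst": ("Hs", "Ht"), "fit": ("Ho", "Ht")}


def _ratio_of_sums(components: pd.DataFrame, coefficient: str, drop: int | None = None) -> float:
    num_col, den_col = _COEFF_PARTS[coefficient]
    sub = components.dropna(subset=[num_col, den_col])
    if drop is not None:
        sub = sub.drop(sub.index[drop])
    den = sub[den_col].sum()
    if den <= 0 or len(sub) == 0:
        return np.nan
    return 1.0 - sub[num_col].sum() / den


def multilocus_jackknife(components: pd.DataFrame, coefficient: str) -> tuple[float, float]:
    """Delete-one-locus jackknife (mean, SE) of a multilocus ratio-of-sums coefficient.

    ``components`` has one row per locus with the relevant columns among
    Ho / Hs / Ht.  The returned mean is the average of the L delete-one
    estimates and SE = sqrt((L-1)/L * sum((theta_l - mean)^2)).
    """
    coefficient = coefficient.lower()
    if coefficient not in _COEFF_PARTS:
        raise ValueError(f"coefficient must be one of {sorted(_COEFF_PARTS)}")
    num_col, den_col = _COEFF_PARTS[coefficient]
    sub = components.dropna(subset=[num_col, den_col])
    L = len(sub)
    if L < 2:
        raise ValueError("jackknife needs >= 2 informative loci")
    thetas = np.array([_ratio_of_sums(sub, coefficient, drop=l) for l in range(L)])
    mean = float(thetas.mean())
    se = float(np.sqrt((L - 1) / L * np.sum((thetas - mean) ** 2)))
    return mean, se


def permutation_test_fst(
    matrix_or_genotypes,
    grouping: str = "variety",
    scheme: PermutationScheme = PermutationScheme(),
    corrected: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for Fst (per locus and multilocus).

    Whole plants are permuted among groups, preserving group sizes;
    p = (1 + #{permuted Fst >= observed}) / (1 + n_permutations).
    """
    model = FStatisticsModel(matrix_or_genotypes, grouping=grouping, corrected=corrected)
    res = model.fit(n_permutations=scheme.n_permutations, seed=scheme.seed)
    out = res.permutation_p.copy()
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class FStatisticsModel:
    """Hierarchical F-statistics on a genotype panel.

    Parameters
    ----------
    data
        A :class:`GenotypePanel`, a :class:`PhenotypeMatrix` (dominant
        mode), or a list of :class:`CodominantGenotype` (codominant mode).
        A panel is scored according to ``mode``; codominant mode restricts
        the panel to its declared-diploid varieties.
    grouping
        ``"variety"`` (default), ``"breeder"`` or ``"ploidy"`` (dominant
        mode only).
    mode
        ``"dominant"`` or ``"codominant"``; inferred from ``data`` when it
        is already scored.
    corrected
        Apply Nei & Chesser small-sample corrections (codominant mode).
    """

    def __init__(self, data, grouping: str = "variety", mode: str | None = None,
                 corrected: bool = False):
        if isinstance(data, GenotypePanel):
            mode = mode or "dominant"
            if mode == "dominant":
                data = to_allelic_phenotype(data)
            elif mode == "codominant":
                diploid = data.subset(ploidy=2)
                data = to_codominant(diploid)
            else:
                raise ValueError(f"unknown mode {mode!r}")
        if isinstance(data, PhenotypeMatrix):
            if mode not in (None, "dominant"):
                raise ValueError("a PhenotypeMatrix is dominant-scored data")
            self.mode = "dominant"
            from .diversity import _group_labels

            self._labels = pd.Categorical(_group_labels(data.meta, grouping))
            self._dd = _DominantData(data)
            self.loci = self._dd.loci
            self.n_plants = self._dd.n_plants
        elif isinstance(data, (list, tuple)) and (not data or isinstance(data[0], CodominantGenotype)):
            if mode not in (None, "codominant"):
                raise ValueError("a CodominantGenotype list is codominant-scored data")
            self.mode = "codominant"
            data = list(data)
            loci = sorted({loc for g in data for loc in g.genotypes})
            self._labels = pd.Categorical(_groups_of(data, grouping))
            self._cd = _CodominantData(data, loci)
            self.loci = loci
            self.n_plants = len(data)
        else:
            raise TypeError(f"cannot build F-statistics model from {type(data)!r}")
        if len(self._labels.categories) < 2:
            raise ValueError("grouping must define >= 2 groups")
        self.grouping = grouping
        self.corrected = corrected
        self.n_groups = len(self._labels.categories)

    # -- internals -----------------------------------------------------
    def _components(self, codes: np.ndarray) -> pd.DataFrame:
        if self.mode == "dominant":
            Hs, Ht = _dominant_hs_ht(self._dd, codes, self.n_groups)
            Ho = np.full_like(Hs, np.nan)
        else:
            Ho, Hs, Ht = _codominant_components(self._cd, codes, self.n_groups, self.corrected)
        return pd.DataFrame({"Ho": Ho, "Hs": Hs, "Ht": Ht}, index=pd.Index(self.loci, name="locus"))

    def _fst_vector(self, codes: np.ndarray) -> tuple[np.ndarray, float]:
        """Per-locus Fst plus the multilocus ratio-of-sums (fast path for permutations)."""
        if self.mode == "dominant":
            Hs, Ht = _dominant_hs_ht(self._dd, codes, self.n_groups)
        else:
            _, Hs, Ht = _codominant_components(self._cd, codes, self.n_groups, self.corrected)
        with np.errstate(divide="ignore", invalid="ignore"):
            per = np.where(Ht > 0, 1.0 - Hs / Ht, np.nan)
        ok = ~(np.isnan(Hs) | np.isnan(Ht))
        den = Ht[ok].sum()
        multi = 1.0 - Hs[ok].sum() / den if den > 0 else np.nan
        return per, multi

    # -- API -----------------------------------------------------------
    def fit(self, n_permutations: int = 0, seed: int | None = None) -> "FStatResults":
        codes = np.asarray(self._labels.codes)
        comp = self._components(codes)
        fis, fst, fit = f_coefficients(comp["Ho"], comp["Hs"], comp["Ht"])
        per_locus = comp.assign(Fis=fis, Fst=fst, Fit=fit)

        multilocus = pd.Series(
            {c: _ratio_of_sums(comp, c) for c in ("fis", "fst", "fit")}, name="multilocus"
        )
        jack = {}
        for c in ("fis", "fst", "fit"):
            num_col, den_col = _COEFF_PARTS[c]
            informative = comp.dropna(subset=[num_col, den_col])
            if len(informative) >= 2:
                jack[c] = multilocus_jackknife(comp, c)
            else:
                jack[c] = (np.nan, np.nan)
        jackknife = pd.DataFrame(jack, index=["mean", "se"]).T

        permutation_p = None
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            obs_per, obs_multi = self._fst_vector(codes)
            count_per = np.zeros(len(self.loci))
            count_multi = 0
            for _ in range(n_permutations):
                perm = rng.permutation(codes)
                per, multi = self._fst_vector(perm)
                with np.errstate(invalid="ignore"):
                    count_per += (per >= obs_per) & ~np.isnan(per) & ~np.isnan(obs_per)
                if not np.isnan(multi) and not np.isnan(obs_multi) and multi >= obs_multi:
                    count_multi += 1
            p_per = (1.0 + count_per) / (1.0 + n_permutations)
            p_per[np.isnan(obs_per)] = np.nan
            permutation_p = pd.DataFrame(
                {"p_fst": np.append(p_per, (1.0 + count_multi) / (1.0 + n_permutations))},
                index=pd.Index(list(self.loci) + ["multilocus"], name="locus"),
            )
        return FStatResults(self, per_locus, multilocus, jackknife, permutation_p,
                            n_permutations, seed)


class FStatResults:
    """Fitted hierarchical F-statistics.

    Attributes
    ----------
    per_locus : DataFrame
        Ho, Hs, Ht, Fis, Fst, Fit per locus (NaN where undefined, e.g. Ho
        and Fis in dominant mode, or a monomorphic locus).
    multilocus : Series
        Ratio-of-sums multilocus fis / fst / fit.
    jackknife : DataFrame
        Delete-one-locus mean and SE per coefficient.
    permutation_p : DataFrame or None
        p-values for Fst per locus and multilocus.
    """

    def __init__(self, model, per_locus, multilocus, jackknife, permutation_p,
                 n_permutations, seed):
        self.model = model
        self.mode = model.mode
        self.grouping = model.grouping
        self.per_locus = per_locus
        self.multilocus = multilocus
        self.jackknife = jackknife
        self.permutation_p = permutation_p
        self.n_permutations = n_permutations
        self.seed = seed

    @property
    def fst(self) -> float:
        return float(self.multilocus["fst"])

    @property
    def fis(self) -> float:
        return float(self.multilocus["fis"])

    @property
    def fit_coefficient(self) -> float:
        return float(self.multilocus["fit"])

    def summary(self) -> str:
        lines = [
            "Hierarchical F-statistics",
            "=" * 60,
            f"mode: {self.mode}   grouping: {self.grouping}   "
            f"groups: {self.model.n_groups}   plants: {self.model.n_plants}",
            "",
            self.per_locus.round(4).to_string(),
            "",
            "Multilocus (ratio of sums over loci):",
        ]
        for c in ("fis", "fst", "fit"):
            v = self.multilocus[c]
            if np.isnan(v):
                continue
            m, se = self.jackknife.loc[c, "mean"], self.jackknife.loc[c, "se"]
            lines.append(f"  {c.capitalize():>4} = {v: .4f}   jackknife {m: .4f} +/- {se:.4f}")
        if self.permutation_p is not None:
            p = self.permutation_p.loc["multilocus", "p_fst"]
            lines.append(
                f"  Fst permutation p = {p:.4g} ({self.n_permutations} whole-plant permutations)"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (optional estimator, codominant diploids)
# ---------------------------------------------------------------------------


def weir_cockerham_theta(
    genotypes: list[CodominantGenotype], grouping: str = "variety"
) -> pd.DataFrame:
    """Weir & Cockerham's theta per locus plus a ratio-of-sums multilocus row.

    Variance-component estimator for codominant diploid data; unlike the
    gene-diversity Fst it weights groups by sample size and can be
    slightly negative near zero differentiation.
    """
    loci = sorted({loc for g in genotypes for loc in g.genotypes})
    labels = pd.Categorical(_groups_of(genotypes, grouping))
    codes = np.asarray(labels.codes)
    n_groups = len(labels.categories)
    cd = _CodominantData(genotypes, loci)
    G = _one_hot(codes, n_groups)
    rows = []
    sum_a = sum_abc = 0.0
    for l, loc in enumerate(loci):
        n_g = G @ cd.valid[l]
        keep = n_g >= 1
        r = int(keep.sum())
        if r < 2:
            rows.append((loc, np.nan))
            continue
        n_i = n_g[keep]
        copies = (G @ cd.cnt[l])[keep]
        p = copies / (2.0 * n_i[:, None])
        # per-group heterozygote counts per allele: a plant is "het for allele i"
        # if it carries exactly one copy of i
        het_i = (G @ (cd.cnt[l] == 1).astype(float))[keep]
        n_bar = n_i.mean()
        n_c = (n_i.sum() - np.sum(n_i**2) / n_i.sum()) / (r - 1)
        a_tot = b_tot = c_tot = 0.0
        for k in range(p.shape[1]):
            p_bar = np.sum(n_i * p[:, k]) / n_i.sum()
            s2 = np.sum(n_i * (p[:, k] - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = np.sum(het_i[:, k]) / n_i.sum()
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2.0
            a_tot += a
            b_tot += b
            c_tot += c
        denom = a_tot + b_tot + c_tot
        theta = a_tot / denom if denom != 0 else np.nan
        sum_a += a_tot
        sum_abc += denom
        rows.append((loc, theta))
    df = pd.DataFrame(rows, columns=["locus", "theta"]).set_index("locus")
    df.loc["multilocus"] = sum_a / sum_abc if sum_abc != 0 else np.nan
    return df


# ---------------------------------------------------------------------------
# dominant vs codominant comparison
# ---------------------------------------------------------------------------


@dataclass
class ScoringComparison:
    """Paired per-locus Fst under dominant vs codominant scoring of the same plants."""

    per_locus: pd.DataFrame  # columns fst_dominant, fst_codominant
    r_squared: float
    multilocus_dominant: float
    multilocus_codominant: float

    @property
    def relative_difference(self) -> float:
        """(codominant - dominant) / dominant multilocus Fst."""
        return self.multilocus_codominant / self.multilocus_dominant - 1.0


def compare_scoring_modes(panel: GenotypePanel, corrected: bool = False) -> ScoringComparison:
    """Dominant vs codominant Fst among declared-diploid varieties.

    Both scorings are computed on the same plant subset: declared-diploid
    plants that pass the three-allele ploidy screen, so that the
    comparison isolates the effect of discarding dosage.
    """
    diploid = panel.subset(ploidy=2)
    suspect = {
        r.plant_id
        for r in detect_ploidy_anomalies(diploid)
        if r.classification == "suspected_triploid"
    }
    clean_ids = [p.plant_id for p in diploid.plants if p.plant_id not in suspect]
    clean = diploid.subset(plant_ids=clean_ids)

    dom = FStatisticsModel(clean, grouping="variety", mode="dominant").fit()
    cod = FStatisticsModel(clean, grouping="variety", mode="codominant",
                           corrected=corrected).fit()
    per = pd.DataFrame(
        {
            "fst_dominant": dom.per_locus["Fst"],
            "fst_codominant": cod.per_locus["Fst"],
        }
    )
    paired = per.dropna()
    if len(paired) < 3:
        raise ValueError("correlation undefined with < 3 informative loci")
    r = np.corrcoef(paired["fst_dominant"], paired["fst_codominant"])[0, 1]
    return ScoringComparison(per, float(r**2), dom.fst, cod.fst)
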