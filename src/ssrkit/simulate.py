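"""Forward simulator of hybrid sugar-beet variety production.

Commercial sugar-beet varieties are F1 hybrids: a diploid cytoplasmic
male-sterile (CMS) mother line is pollinated by a selected father line
which is either diploid (giving a diploid variety) or tetraploid (giving a
triploid variety).  The simulator mirrors that system:

* panel-wide *base* allele frequencies per locus (skewed Dirichlet draw);
* per breeder, a gene pool diverged from the base by a Balding-Nichols
  draw at ``breeder_divergence``;
* per variety, a mother line and a father line each diverged from the
  breeder pool at ``line_divergence`` (with ``paired_pools=False`` the two
  lines coincide, turning each variety into a single random-mating island
  — the configuration used for island-model parameter recovery);
* diploid plants receive one maternal and one paternal allele per locus;
  triploid plants receive one maternal allele plus a two-allele gamete
  sampled without replacement from a simulated autotetraploid father (no
  double reduction);
* artifacts: per-locus null alleles (an extra invisible allele segregating
  at the configured frequency; a plant whose whole call is null becomes a
  dropout), random amplification dropouts, and tetraploid-pollen
  contamination that silently turns a diploid-variety seed into a triploid.

Every run is exactly reproducible from (config, seed), and the emitted
:class:`GroundTruth` records pools, gametes, true ploidies and artifact
assignments so downstream statistics can be audited against truth.

The default configuration reproduces the reference study conditions: the
published 40-variety layout (11 diploid, 29 triploid) x 30 plants x 12
loci with the published per-locus allele counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import reference
from .panel import GenotypePanel, Locus, PlantRecord, _label_sequence, write_panel

__all__ = [
    "VarietySpec",
    "SimulationConfig",
    "Pools",
    "GroundTruth",
    "simulate_pools",
    "simulate_variety",
    "inject_artifacts",
    "simulate_panel",
    "emit",
    "default_varieties",
]

NULL = -1  # sentinel allele index for a null (non-amplifying) allele


@dataclass(frozen=True)
class VarietySpec:
    """One variety to simulate: name, breeder, ploidy (2 or 3), plants."""

    name: str
    breeder: str
    ploidy: int
    n_plants: int = 30

    def __post_init__(self):
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")


def default_varieties() -> list[VarietySpec]:
    """The published 40-variety layout (breeder and ploidy per variety)."""
    return [
        VarietySpec(v, b, p) for v, (b, p, _, _) in reference.VARIETY_ROWS.items()
    ]


@dataclass
class SimulationConfig:
    """Parameters of one simulated panel; ``seed`` is mandatory.

    ``alleles_per_locus`` — explicit per-locus allele counts (defaults to
    the published panel counts when ``n_loci`` is 12, otherwise drawn
    uniformly from ``allele_range``).  ``breeder_divergence`` and
    ``line_divergence`` are Balding-Nichols F targets for breeder pools
    around the base frequencies and parental lines around the breeder
    pool.  ``paired_pools=False`` collapses each variety's mother and
    father line into a single pool (island model).  Artifact rates are
    probabilities in [0, 1]; ``null_allele_freq`` may be a scalar or a
    per-locus sequence.
    """

    seed: int
    n_loci: int = 12
    allele_range: tuple[int, int] = (3, 21)
    alleles_per_locus: tuple[int, ...] | None = None
    varieties: list[VarietySpec] = field(default_factory=default_varieties)
    breeder_divergence: float = 0.06
    line_divergence: float = 0.15
    paired_pools: bool = True
    base_dirichlet: float = 0.25
    null_allele_freq: float | tuple[float, ...] = 0.0
    dropout_rate: float = 0.01
    contamination_rate: float = 0.0

    def __post_init__(self):
        if self.allele_range[0] < 1 or self.allele_range[0] > self.allele_range[1]:
            raise ValueError("infeasible allele_range")
        if self.alleles_per_locus is None and self.n_loci == 12:
            self.alleles_per_locus = tuple(reference.PANEL_ALLELE_COUNTS)
        if self.alleles_per_locus is not None:
            if len(self.alleles_per_locus) != self.n_loci:
                raise ValueError("alleles_per_locus length must equal n_loci")
            if min(self.alleles_per_locus) < 1:
                raise ValueError("infeasible allele count < 1")
        for rate in (self.dropout_rate, self.contamination_rate,
                     self.breeder_divergence, self.line_divergence):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates and divergences must lie in [0, 1]")
        for r in np.atleast_1d(np.asarray(self.null_allele_freq, dtype=float)):
            if not (0.0 <= r < 1.0):
                raise ValueError("null_allele_freq must lie in [0, 1)")

    def null_freqs(self) -> np.ndarray:
        r = np.asarray(self.null_allele_freq, dtype=float)
        return np.full(self.n_loci, float(r)) if r.ndim == 0 else r


@dataclass
class Pools:
    """Frequency hierarchy: base -> breeder pools -> per-variety parental lines.

    Frequencies are over visible alleles 0..k-1; when a locus carries a
    null allele its frequency occupies the *last* slot and the visible
    slots are downscaled accordingly.
    """

    locus_names: list[str]
    n_alleles: list[int]  # visible alleles per locus
    lengths: list[np.ndarray]  # fragment lengths per locus (visible alleles)
    base: list[np.ndarray]
    breeder: dict  # breeder -> list of per-locus freq arrays
    mother: dict  # variety -> list of per-locus freq arrays
    father: dict
    null_freq: np.ndarray  # per locus


@dataclass
class GroundTruth:
    """Everything the generator knows that the genotype file does not."""

    config: SimulationConfig
    pools: Pools
    true_ploidy: dict  # plant_id -> 2 or 3
    contaminated: list  # plant ids sired by stray tetraploid pollen
    gametes: dict  # plant_id -> list per locus of allele-index tuples (maternal first)
    dropouts: list  # (plant_id, locus) pairs dropped at random
    null_masked: list  # (plant_id, locus) pairs that became dropouts through nulls


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols style frequency draw: Dirichlet(p * (1-f)/f), E = p, Var = f p(1-p)."""
    if f <= 0.0:
        return p.copy()
    alpha = np.maximum(p, 1e-9) * (1.0 - f) / f
    return rng.dirichlet(alpha)


def simulate_pools(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pools:
    """Draw the base / breeder / parental-line frequency hierarchy."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.alleles_per_locus is not None:
        counts = list(config.alleles_per_locus)
    else:
        lo, hi = config.allele_range
        counts = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_loci)]
    if config.n_loci == 12 and counts == list(reference.PANEL_ALLELE_COUNTS):
        names = list(reference.LOCI)
        ranges = [reference.ALLELE_LENGTH_RANGES[n] for n in names]
    else:
        names = [f"loc{i + 1:02d}" for i in range(config.n_loci)]
        ranges = [(100 + 10 * i, 100 + 10 * i + 4 * counts[i] + 20) for i in range(config.n_loci)]
    lengths = []
    for k, (lo_bp, hi_bp) in zip(counts, ranges):
        span = np.arange(lo_bp, hi_bp + 1)
        lengths.append(np.sort(rng.choice(span, size=min(k, span.size), replace=False)))
        if lengths[-1].size < k:  # range narrower than allele count: extend upward
            extra = np.arange(hi_bp + 1, hi_bp + 1 + (k - lengths[-1].size))
            lengths[-1] = np.concatenate([lengths[-1], extra])

    base = [rng.dirichlet(np.full(k, config.base_dirichlet)) for k in counts]
    nulls = config.null_freqs()
    # visible frequencies downscaled; null occupies an extra hidden slot
    base_full = [
        np.concatenate([p * (1.0 - r), [r]]) if r > 0 else p
        for p, r in zip(base, nulls)
    ]
    breeders = sorted({v.breeder for v in config.varieties})
    breeder_pools = {
        b: [_bn_draw(rng, p, config.breeder_divergence) for p in base_full]
        for b in breeders
    }
    mother, father = {}, {}
    for v in config.varieties:
        bp = breeder_pools[v.breeder]
        mother[v.name] = [_bn_draw(rng, p, config.line_divergence) for p in bp]
        father[v.name] = (
            [_bn_draw(rng, p, config.line_divergence) for p in bp]
            if config.paired_pools
            else [p.copy() for p in mother[v.name]]
        )
    return Pools(names, counts, lengths, base_full, breeder_pools, mother, father, nulls)


def _draw(rng, freqs: np.ndarray, size) -> np.ndarray:
    """Allele-index draws; the hidden null slot maps to the NULL sentinel."""
    k = freqs.size
    out = rng.choice(k, size=size, p=freqs)
    return out


def _mark_null(idx: np.ndarray, n_visible: int) -> np.ndarray:
    return np.where(idx >= n_visible, NULL, idx)


def simulate_variety(
    pools: Pools, spec: VarietySpec, rng: np.random.Generator
) -> dict:
    """Gametes for every plant of one variety: plant -> per-locus allele tuples.

    A diploid plant gets (maternal, paternal); a triploid gets (maternal,
    paternal, paternal) where the two paternal alleles are a gamete of an
    autotetraploid father (4 independent pool draws, 2 retained without
    replacement).
    """
    if spec.name not in pools.mother:
        raise KeyError(f"no pools for variety {spec.name!r}")
    n = spec.n_plants
    out: dict = {}
    per_locus = []
    for l, k in enumerate(pools.n_alleles):
        pm = pools.mother[spec.name][l]
        pf = pools.father[spec.name][l]
        m = _mark_null(_draw(rng, pm, n), k)
        if spec.ploidy == 2:
            f = _mark_null(_draw(rng, pf, n), k)
            per_locus.append(np.stack([m, f], axis=1))
        else:
            tetra = _mark_null(_draw(rng, pf, (n, 4)), k)
            pick = np.argsort(rng.random((n, 4)), axis=1)[:, :2]
            gam = np.take_along_axis(tetra, pick, axis=1)
            per_locus.append(np.column_stack([m, gam]))
    for i in range(n):
        out[f"{spec.name}-{i + 1:02d}"] = [pl[i] for pl in per_locus]
    return out


def inject_artifacts(
    gametes: dict,
    pools: Pools,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict, dict, list, list, list]:
    """Apply contamination, then express nulls and random dropouts.

    Contamination: with probability ``contamination_rate`` a plant of a
    declared-diploid variety is re-sired by a tetraploid donor drawn from
    a random triploid variety's father line (or the base frequencies when
    the panel has no triploid variety), making it a true triploid.

    Returns (calls, true_ploidy, contaminated, dropouts, null_masked)
    where calls maps plant_id -> list per locus of visible allele-index
    sets (None = dropout).
    """
    specs = {v.name: v for v in config.varieties}
    triploid_varieties = [v.name for v in config.varieties if v.ploidy == 3]
    true_ploidy, contaminated = {}, []
    calls: dict = {}
    dropouts, null_masked = [], []
    for pid, per_locus in gametes.items():
        vname = pid.rsplit("-", 1)[0]
        spec = specs[vname]
        ploidy = spec.ploidy
        if spec.ploidy == 2 and config.contamination_rate > 0 and rng.random() < config.contamination_rate:
            donor = (
                pools.father[str(rng.choice(triploid_varieties))]
                if triploid_varieties
                else pools.base
            )
            new = []
            for l, k in enumerate(pools.n_alleles):
                tetra = _mark_null(_draw(rng, donor[l], 4), k)
                pick = rng.permutation(4)[:2]
                new.append(np.array([per_locus[l][0], tetra[pick[0]], tetra[pick[1]]]))
            per_locus = new
            gametes[pid] = per_locus
            ploidy = 3
            contaminated.append(pid)
        true_ploidy[pid] = ploidy
        plant_calls = []
        for l, alleles in enumerate(per_locus):
            visible = sorted({int(a) for a in alleles if a != NULL})
            if not visible:
                plant_calls.append(None)
                null_masked.append((pid, pools.locus_names[l]))
            elif config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                plant_calls.append(None)
                dropouts.append((pid, pools.locus_names[l]))
            else:
                plant_calls.append(set(visible))
        calls[pid] = plant_calls
    return calls, true_ploidy, contaminated, dropouts, null_masked


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, GroundTruth]:
    """Run the full generator: pools -> crosses -> artifacts -> panel + truth."""
    rng = np.random.default_rng(config.seed)
    pools = simulate_pools(config, rng)
    gametes: dict = {}
    for spec in config.varieties:
        gametes.update(simulate_variety(pools, spec, rng))
    calls, true_ploidy, contaminated, dropouts, null_masked = inject_artifacts(
        gametes, pools, config, rng
    )
    loci = []
    labels_per_locus = []
    for name, k, lens in zip(pools.locus_names, pools.n_alleles, pools.lengths):
        labels = _label_sequence(k)
        labels_per_locus.append(labels)
        loci.append(Locus(name, tuple(labels), dict(zip(labels, (int(x) for x in lens)))))
    plants = []
    for spec in config.varieties:
        for i in range(spec.n_plants):
            pid = f"{spec.name}-{i + 1:02d}"
            call_map = {}
            for l, name in enumerate(pools.locus_names):
                c = calls[pid][l]
                call_map[name] = (
                    None if c is None else frozenset(labels_per_locus[l][a] for a in c)
                )
            plants.append(PlantRecord(pid, spec.name, spec.breeder, spec.ploidy, call_map))
    panel = GenotypePanel(loci, plants)
    truth = GroundTruth(
        config, pools, true_ploidy, contaminated,
        {pid: [tuple(int(a) for a in arr) for arr in per] for pid, per in gametes.items()},
        dropouts, null_masked,
    )
    return panel, truth


def emit(panel: GenotypePanel, truth: GroundTruth, out_dir) -> dict:
    """Write genotypes.csv (native dialect) + ground_truth.json; deterministic given seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = out / "genotypes.csv"
    write_panel(panel, geno)
    gt = out / "ground_truth.json"
    cfg = asdict(truth.config)
    cfg["varieties"] = [asdict(v) for v in truth.config.varieties]
    payload = {
        "config": cfg,
        "true_ploidy": truth.true_ploidy,
        "contaminated": truth.contaminated,
        "dropouts": [list(x) for x in truth.dropouts],
        "null_masked": [list(x) for x in truth.null_masked],
        "pool_base_frequencies": {
            name: [float(x) for x in p]
            for name, p in zip(truth.pools.locus_names, truth.pools.base)
        },
        "gametes": {pid: [list(g) for g in per] for pid, per in truth.gametes.items()},
    }
    with open(gt, "w") as fh:
        json.dump(payload, fh, indent=0, sort_keys=True)
    return {"genotypes": geno, "ground_truth": gt}
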