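"""Genotype panel data model and I/O for mixed-ploidy microsatellite surveys.

A *panel* is the unit of analysis: a set of plants, each belonging to a
named variety (with a breeder and a declared ploidy of 2 or 3), scored at a
common set of microsatellite loci.  A call at a locus is the *set* of
distinct allele labels observed for that plant — dosage is not recorded, so
a triploid carrying A, A, B and a diploid carrying A, B both yield the call
``{A, B}``.  An empty amplification (dropout) is recorded as missing and is
distinguishable from a monomorphic call.

The native on-disk format is a plain CSV dialect::

    plant_id,variety,breeder,ploidy,<locus1>,<locus2>,...
    P1,VarA,KWS,2,201;293,135,

where each locus cell holds semicolon-separated integer fragment lengths in
base pairs and an empty cell means dropout.  Allele labels (``a``, ``b``,
``c``, ...) are attached to lengths either in first-seen order at read time
or by calibration against designated reference varieties
(:func:`calibrate_alleles`).
"""

from __future__ import annotations

import csv
import io
import string
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "PlantRecord",
    "GenotypePanel",
    "PhenotypeMatrix",
    "CalibrationReport",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "calibrate_alleles",
    "write_matrix",
    "write_square_distance",
    "write_newick",
    "read_newick",
]

MISSING_CODE = "NA"

VALID_PLOIDIES = (2, 3)


class PanelFormatError(ValueError):
    """Malformed genotype file (named line in the message)."""


class PanelValidationError(ValueError):
    """Structurally invalid panel (duplicate ids, unknown ploidy, ...)."""


def _label_sequence(n: int) -> list[str]:
    """Allele labels a..z, then aa, ab, ... (registry order)."""
    letters = string.ascii_lowercase
    out: list[str] = []
    i = 0
    while len(out) < n:
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[(i // 26) - 1] + letters[i % 26])
        i += 1
    return out


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker with its allele registry.

    ``alleles`` is the registry in fixed order (calibration order); each
    label maps to a fragment length in base pairs.  Labels are unique and
    lengths strictly positive.
    """

    name: str
    alleles: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise PanelValidationError(f"duplicate allele labels at locus {self.name}")
        for lab in self.alleles:
            if lab not in self.lengths:
                raise PanelValidationError(f"label {lab!r} unregistered at {self.name}")
            if not (int(self.lengths[lab]) > 0):
                raise PanelValidationError(
                    f"non-positive length for {self.name}.{lab}: {self.lengths[lab]}"
                )

    def label_of(self, length: int) -> str | None:
        for lab, ln in self.lengths.items():
            if ln == length:
                return lab
        return None


@dataclass(frozen=True)
class PlantRecord:
    """One genotyped plant: metadata plus per-locus call sets.

    ``calls`` maps locus name to a frozenset of allele labels, or ``None``
    for an amplification dropout at that locus.
    """

    plant_id: str
    variety: str
    breeder: str
    declared_ploidy: int
    calls: Mapping[str, frozenset | None]

    def call(self, locus: str) -> frozenset | None:
        return self.calls.get(locus)


@dataclass(frozen=True)
class CalibrationReport:
    """Outcome of reference-variety allele calibration.

    ``unmatched`` lists (locus, length) pairs observed in the panel but
    absent from every reference variety; these keep provisional labels of
    the form ``?<length>``.
    """

    reference_varieties: tuple[str, ...]
    unmatched: tuple[tuple[str, int], ...]


class GenotypePanel:
    """Validated container of loci + plants (see module docstring)."""

    def __init__(
        self,
        loci: Sequence[Locus],
        plants: Sequence[PlantRecord],
        calibration: CalibrationReport | None = None,
    ) -> None:
        if len(loci) < 1 or len(plants) < 1:
            raise PanelValidationError("panel needs at least 1 locus and 1 plant")
        self.loci: tuple[Locus, ...] = tuple(loci)
        self.plants: tuple[PlantRecord, ...] = tuple(plants)
        self.calibration = calibration
        self._validate()

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        ids = [p.plant_id for p in self.plants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate plant_id(s): {dup[:5]}")
        by_locus = {l.name: set(l.alleles) for l in self.loci}
        meta: dict[str, tuple[str, int]] = {}
        for p in self.plants:
            if p.declared_ploidy not in VALID_PLOIDIES:
                raise PanelValidationError(
                    f"plant {p.plant_id}: ploidy {p.declared_ploidy} not in {VALID_PLOIDIES}"
                )
            prev = meta.setdefault(p.variety, (p.breeder, p.declared_ploidy))
            if prev != (p.breeder, p.declared_ploidy):
                raise PanelValidationError(
                    f"variety {p.variety}: inconsistent breeder/ploidy metadata"
                )
            for loc, call in p.calls.items():
                if loc not in by_locus:
                    raise PanelValidationError(f"plant {p.plant_id}: unknown locus {loc}")
                if call is not None and not call <= by_locus[loc]:
                    bad = sorted(call - by_locus[loc])
                    raise PanelValidationError(
                        f"plant {p.plant_id}: unregistered allele(s) {bad} at {loc}"
                    )
        self._variety_meta = meta

    # -- accessors -----------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def varieties(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.plants:
            seen.setdefault(p.variety, None)
        return list(seen)

    @property
    def variety_meta(self) -> dict[str, tuple[str, int]]:
        """variety -> (breeder, declared_ploidy)."""
        return dict(self._variety_meta)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def subset(
        self,
        varieties: Iterable[str] | None = None,
        ploidy: int | None = None,
        plant_ids: Iterable[str] | None = None,
    ) -> "GenotypePanel":
        """Restrict to given varieties / declared ploidy / plants."""
        vset = set(varieties) if varieties is not None else None
        pset = set(plant_ids) if plant_ids is not None else None
        keep = [
            p
            for p in self.plants
            if (vset is None or p.variety in vset)
            and (ploidy is None or p.declared_ploidy == ploidy)
            and (pset is None or p.plant_id in pset)
        ]
        if not keep:
            raise PanelValidationError("subset selects no plants")
        return GenotypePanel(self.loci, keep, self.calibration)

    def __len__(self) -> int:
        return len(self.plants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            [(l.name, l.alleles, dict(l.lengths)) for l in self.loci]
            == [(l.name, l.alleles, dict(l.lengths)) for l in other.loci]
        ) and (
            [(p.plant_id, p.variety, p.breeder, p.declared_ploidy, dict(p.calls)) for p in self.plants]
            == [(p.plant_id, p.variety, p.breeder, p.declared_ploidy, dict(p.calls)) for p in other.plants]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypePanel {len(self.plants)} plants, {len(self.loci)} loci, "
            f"{len(self.varieties)} varieties>"
        )


class PhenotypeMatrix:
    """Plants x (locus, allele) binary presence matrix with a missing mask.

    ``data`` is a DataFrame indexed by plant_id with a (locus, allele)
    MultiIndex over columns and uint8 values; ``missing`` is a plant x locus
    boolean DataFrame flagging dropouts; ``meta`` carries variety, breeder
    and declared ploidy per plant.  For a non-missing (plant, locus) at
    least one column of that locus is 1.
    """

    def __init__(self, data: pd.DataFrame, missing: pd.DataFrame, meta: pd.DataFrame):
        if not set(np.unique(data.to_numpy())) <= {0, 1}:
            raise PanelValidationError("phenotype matrix values must be 0/1")
        self.data = data.astype(np.uint8)
        self.missing = missing.astype(bool)
        self.meta = meta
        loci = list(dict.fromkeys(data.columns.get_level_values(0)))
        if set(missing.columns) != set(loci):
            raise PanelValidationError("missing-mask columns must match matrix loci")
        self.locus_names = loci
        # consistency: non-missing entries show at least one presence
        for loc in loci:
            block = self.data[loc].to_numpy()
            ok = (block.sum(axis=1) >= 1) | self.missing[loc].to_numpy()
            if not ok.all():
                bad = data.index[~ok][0]
                raise PanelValidationError(
                    f"plant {bad}: locus {loc} non-missing but no allele present"
                )

    @property
    def plant_ids(self) -> list[str]:
        return list(self.data.index)

    def locus_block(self, locus: str) -> pd.DataFrame:
        return self.data[locus]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhenotypeMatrix {self.data.shape[0]} plants x {self.data.shape[1]} alleles>"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ("plant_id", "variety", "breeder", "ploidy")


def _parse_cell(cell: str, line_no: int, locus: str) -> tuple[int, ...] | None:
    cell = cell.strip()
    if cell == "" or cell == MISSING_CODE:
        return None
    lengths = []
    for tok in cell.split(";"):
        tok = tok.strip()
        try:
            v = int(tok)
        except ValueError:
            raise PanelFormatError(
                f"line {line_no}: locus {locus}: non-integer length {tok!r}"
            ) from None
        if v <= 0:
            raise PanelFormatError(f"line {line_no}: locus {locus}: length {v} <= 0")
        lengths.append(v)
    if len(set(lengths)) != len(lengths):
        warnings.warn(
            f"line {line_no}: locus {locus}: repeated length(s) collapsed (set semantics)",
            stacklevel=2,
        )
    return tuple(dict.fromkeys(lengths))


def read_panel(path, dialect: str = "native_csv") -> GenotypePanel:
    """Read a genotype panel from the native CSV dialect.

    Allele labels are assigned per locus in first-seen order; call
    :func:`calibrate_alleles` afterwards to re-anchor labels on reference
    varieties.
    """
    if dialect != "native_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        return _read_panel_stream(fh)


def _read_panel_stream(fh) -> GenotypePanel:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise PanelFormatError("empty file") from None
    header = [h.strip() for h in header]
    if tuple(header[:4]) != _META_COLS:
        raise PanelFormatError(
            f"header must start with {','.join(_META_COLS)}; got {header[:4]}"
        )
    locus_names = header[4:]
    if not locus_names:
        raise PanelFormatError("header declares no loci")
    seen_lengths: dict[str, list[int]] = {ln: [] for ln in locus_names}
    rows = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(c.strip() == "" for c in row):
            continue
        if len(row) != len(header):
            raise PanelFormatError(
                f"line {line_no}: expected {len(header)} fields, got {len(row)}"
            )
        pid, variety, breeder, ploidy_s = (c.strip() for c in row[:4])
        try:
            ploidy = int(ploidy_s)
        except ValueError:
            raise PanelValidationError(
                f"line {line_no}: unknown ploidy value {ploidy_s!r}"
            ) from None
        if ploidy not in VALID_PLOIDIES:
            raise PanelValidationError(f"line {line_no}: unknown ploidy value {ploidy}")
        calls: dict[str, tuple[int, ...] | None] = {}
        for loc, cell in zip(locus_names, row[4:]):
            lengths = _parse_cell(cell, line_no, loc)
            calls[loc] = lengths
            if lengths:
                for v in lengths:
                    if v not in seen_lengths[loc]:
                        seen_lengths[loc].append(v)
        rows.append((line_no, pid, variety, breeder, ploidy, calls))

    if not rows:
        raise PanelFormatError("file contains no data rows")
    ids = [r[1] for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise PanelValidationError(f"duplicate plant_id(s): {dup[:5]}")

    loci = []
    label_by_length: dict[str, dict[int, str]] = {}
    for loc in locus_names:
        lens = seen_lengths[loc]
        labels = _label_sequence(len(lens)) if lens else ()
        label_by_length[loc] = dict(zip(lens, labels))
        loci.append(Locus(loc, tuple(labels), dict(zip(labels, lens))))

    plants = []
    for _line, pid, variety, breeder, ploidy, calls in rows:
        labelled = {
            loc: (None if lv is None else frozenset(label_by_length[loc][v] for v in lv))
            for loc, lv in calls.items()
        }
        plants.append(PlantRecord(pid, variety, breeder, ploidy, labelled))
    return GenotypePanel(loci, plants)


def write_panel(panel: GenotypePanel, path) -> None:
    """Write a panel back to the native CSV dialect (lengths, not labels)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_META_COLS) + panel.locus_names)
        for p in panel.plants:
            cells = []
            for loc in panel.loci:
                call = p.calls.get(loc.name)
                if call is None:
                    cells.append("")
                else:
                    lens = sorted(loc.lengths[a] for a in call)
                    cells.append(";".join(str(v) for v in lens))
            w.writerow([p.plant_id, p.variety, p.breeder, p.declared_ploidy] + cells)


def calibrate_alleles(
    panel: GenotypePanel, reference: Iterable[str] = ()
) -> GenotypePanel:
    """Re-anchor allele labels on reference varieties.

    Lengths present in the reference varieties get labels ``a``, ``b``, ...
    in ascending length order (the calibration ladder); any panel length
    absent from every reference gets a provisional ``?<length>`` label and
    is listed in the returned panel's :class:`CalibrationReport`.  With an
    empty reference set, labels are assigned by ascending length panel-wide.
    Idempotent: labels are a pure function of lengths.
    """
    reference = tuple(reference)
    known = set(panel.varieties)
    missing_ref = [v for v in reference if v not in known]
    if missing_ref:
        raise PanelValidationError(f"reference varieties not in panel: {missing_ref}")

    ref_plants = [p for p in panel.plants if not reference or p.variety in reference]
    new_loci = []
    relabel: dict[str, dict[str, str]] = {}
    unmatched: list[tuple[str, int]] = []
    for loc in panel.loci:
        ref_lengths: set[int] = set()
        for p in ref_plants:
            call = p.calls.get(loc.name)
            if call:
                ref_lengths.update(loc.lengths[a] for a in call)
        all_lengths = sorted(loc.lengths[a] for a in loc.alleles)
        anchored = sorted(l for l in all_lengths if l in ref_lengths or not reference)
        labels = _label_sequence(len(anchored))
        length_to_label = dict(zip(anchored, labels))
        for l in all_lengths:
            if l not in length_to_label:
                length_to_label[l] = f"?{l}"
                unmatched.append((loc.name, l))
        ordered = sorted(all_lengths, key=lambda l: (length_to_label[l].startswith("?"), l))
        new_labels = tuple(length_to_label[l] for l in ordered)
        new_loci.append(Locus(loc.name, new_labels, {length_to_label[l]: l for l in ordered}))
        relabel[loc.name] = {a: length_to_label[loc.lengths[a]] for a in loc.alleles}

    new_plants = [
        replace(
            p,
            calls={
                loc: (None if call is None else frozenset(relabel[loc][a] for a in call))
                for loc, call in p.calls.items()
            },
        )
        for p in panel.plants
    ]
    report = CalibrationReport(reference, tuple(sorted(unmatched)))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} allele length(s) not present in reference varieties; "
            "kept under provisional labels",
            stacklevel=2,
        )
    return GenotypePanel(new_loci, new_plants, calibration=report)


def write_matrix(matrix: PhenotypeMatrix, path) -> None:
    """Write a presence/absence matrix as CSV with locus.allele columns.

    Cells of a missing (plant, locus) are written as the explicit code
    ``NA`` rather than 0, so absence and dropout stay distinguishable.
    """
    out = matrix.data.astype(object).copy()
    for loc in matrix.locus_names:
        miss = matrix.missing[loc]
        for col in out[loc].columns:
            out.loc[miss, (loc, col)] = MISSING_CODE
    out.columns = [f"{loc}.{al}" for loc, al in out.columns]
    out.index.name = "plant_id"
    out.to_csv(path)


def write_square_distance(labels: Sequence[str], d: np.ndarray, path) -> None:
    """Write a PHYLIP square distance matrix; NaN entries become -1.0 with a warning."""
    d = np.asarray(d, dtype=float)
    if d.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if np.isnan(d).any():
        warnings.warn("distance matrix has undefined entries; writing sentinel -1.0")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, d):
            cells = " ".join("-1.000000" if np.isnan(v) else f"{v:.6f}" for v in row)
            fh.write(f"{lab}  {cells}\n")


def write_newick(tree, path) -> None:
    """Write a scikit-bio TreeNode as Newick with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path):
    """Read a Newick file into a scikit-bio TreeNode."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
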