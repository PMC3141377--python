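"""Text-format I/O for the dissection-comparison pipeline.

Expression matrices travel as GCT (tab-separated, self-describing header)
with a companion CLS class-label file; gene sets as GMT; probe-level array
CGH as a flat four-column TSV sorted by (patient, chromosome, position);
probe-to-gene maps as a two-column TSV; gene coordinates as BED.  All
formats are UTF-8 and round-trip exactly.

Gene and sample identifiers are opaque, case-sensitive strings.  Genomic
coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

CLASS_LABELS = ("cancer", "normal")
METHOD_LABELS = ("macro", "micro", "none")


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.name:
            raise FormatError("gene set needs a non-empty name")
        if any(not m for m in self.members):
            raise FormatError(f"gene set {self.name!r} has a blank member id")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


class ExpressionMatrix:
    """Genes x samples log2 intensities with per-sample class/method labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_class
        ``cancer`` / ``normal`` per sample (sequence or Series aligned to
        the sample columns).
    sample_method
        ``macro`` / ``micro`` / ``none`` per sample; default ``none``.
    patient_id
        Optional per-sample patient identifier linking macro/micro pairs.
    """

    def __init__(self, values: pd.DataFrame, sample_class, sample_method=None,
                 patient_id=None):
        values = values.astype(float)
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if not np.isfinite(values.to_numpy()).all():
            raise FormatError("expression values must be finite")
        self.values = values
        self.sample_class = self._align("class", sample_class, CLASS_LABELS)
        self.sample_method = self._align(
            "method", sample_method if sample_method is not None else "none",
            METHOD_LABELS)
        if patient_id is None:
            self.patient_id = None
        else:
            pid = patient_id
            if not isinstance(pid, pd.Series):
                pid = pd.Series(list(pid), index=values.columns)
            self.patient_id = pid.reindex(values.columns).astype(str)

    def _align(self, what: str, labels, allowed) -> pd.Series:
        cols = self.values.columns
        if isinstance(labels, str):
            labels = [labels] * len(cols)
        if isinstance(labels, pd.Series):
            ser = labels.reindex(cols)
            if ser.isna().any():
                raise FormatError(f"every sample needs a {what} label")
        else:
            labels = list(labels)
            if len(labels) != len(cols):
                raise FormatError(
                    f"{what} labels ({len(labels)}) do not match sample "
                    f"count ({len(cols)})")
            ser = pd.Series(labels, index=cols)
        bad = sorted(set(ser) - set(allowed))
        if bad:
            raise FormatError(f"unknown {what} label(s): {bad}")
        return ser.astype(str)

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_class(self, label: str) -> list:
        return self.sample_class.index[self.sample_class == label].tolist()

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids], self.sample_class[ids],
            self.sample_method[ids],
            None if self.patient_id is None else self.patient_id[ids])

    @staticmethod
    def combine(*mats: "ExpressionMatrix") -> "ExpressionMatrix":
        """Column-concatenate matrices sharing an identical gene index."""
        first = mats[0]
        for m in mats[1:]:
            if not first.values.index.equals(m.values.index):
                raise FormatError("matrices do not share the same gene index")
        values = pd.concat([m.values for m in mats], axis=1)
        cls = pd.concat([m.sample_class for m in mats])
        met = pd.concat([m.sample_method for m in mats])
        if any(m.patient_id is None for m in mats):
            pid = None
        else:
            pid = pd.concat([m.patient_id for m in mats])
        return ExpressionMatrix(values, cls, met, pid)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        same = (self.values.equals(other.values)
                and self.sample_class.equals(other.sample_class)
                and self.sample_method.equals(other.sample_method))
        if self.patient_id is None or other.patient_id is None:
            return same and self.patient_id is other.patient_id
        return same and self.patient_id.equals(other.patient_id)


@dataclass
class CGHProfile:
    """Ordered probe-level log2 tumor/reference ratios for one patient."""

    patient_id: str
    probes: pd.DataFrame  # columns: chromosome, position, log2_ratio

    def __post_init__(self):
        need = ["chromosome", "position", "log2_ratio"]
        if list(self.probes.columns[:3]) != need:
            self.probes = self.probes[need]
        self.probes = self.probes.reset_index(drop=True)
        for chrom, grp in self.probes.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise FormatError(
                    f"probe positions not strictly increasing on "
                    f"chromosome {chrom} of patient {self.patient_id}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# GCT / CLS


def read_expression(path, class_path, method=None, patient_id=None) -> ExpressionMatrix:
    """Read a GCT matrix plus a CLS class file into an ExpressionMatrix.

    The CLS sample count must match the matrix; labels may be literal
    class names or 0-based indices into the names on the ``#`` line.
    """
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise FormatError(f"{path}: not a GCT file (missing #1.x header)")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", dtype={0: str})
    if table.shape[0] != n_rows or table.shape[1] - 2 != n_cols:
        raise FormatError(
            f"{path}: GCT header declares {n_rows}x{n_cols} but table is "
            f"{table.shape[0]}x{table.shape[1] - 2}")
    genes = table.iloc[:, 0].astype(str)
    data = table.iloc[:, 2:]
    try:
        data = data.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    values = data.set_axis(genes, axis=0)
    values.index.name = None
    classes = read_class_labels(class_path)
    if len(classes) != values.shape[1]:
        raise FormatError(
            f"{class_path}: {len(classes)} class labels for "
            f"{values.shape[1]} samples in {path}")
    return ExpressionMatrix(values, classes, method, patient_id)


def read_class_labels(path) -> list:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) < 3:
            raise FormatError(f"{path}: malformed CLS header line")
        n_samples = int(header[0])
        names_line = fh.readline().split()
        if not names_line or names_line[0] != "#":
            raise FormatError(f"{path}: CLS second line must start with '#'")
        names = names_line[1:]
        labels = fh.readline().split()
    if len(labels) != n_samples:
        raise FormatError(
            f"{path}: CLS declares {n_samples} samples but lists "
            f"{len(labels)} labels")
    out = []
    for lab in labels:
        if lab in names:
            out.append(lab)
        elif lab.isdigit() and int(lab) < len(names):
            out.append(names[int(lab)])
        else:
            raise FormatError(f"{path}: unknown class label {lab!r}")
    return out


def write_expression(matrix: ExpressionMatrix, path, class_path) -> None:
    """Write GCT + CLS; inverse of :func:`read_expression`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.values.iterrows():
            cells = "\t".join(repr(float(v)) for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{cells}\n")
    with open(class_path, "w", encoding="utf-8") as fh:
        order = list(dict.fromkeys(matrix.sample_class))
        fh.write(f"{matrix.n_samples} {len(order)} 1\n")
        fh.write("# " + " ".join(order) + "\n")
        fh.write(" ".join(matrix.sample_class) + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gene_sets(path) -> list:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets, seen = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members)")
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(name, members))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write(gs.name + "\tna\t" + "\t".join(sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# probe-level CGH TSV


CGH_COLUMNS = ["patient_id", "chromosome", "position", "log2_ratio"]


def read_cgh(path) -> list:
    """Read a probe-level CGH TSV into one CGHProfile per patient.

    Rows must be grouped by patient and sorted by (chromosome, position)
    within each patient; positions are 1-based.
    """
    table = pd.read_csv(path, sep="\t", dtype={"patient_id": str,
                                               "chromosome": str})
    missing = [c for c in CGH_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing CGH columns {missing}")
    profiles = []
    for pid, grp in table.groupby("patient_id", sort=False):
        profiles.append(CGHProfile(str(pid), grp[CGH_COLUMNS[1:]]))
    return profiles


def write_cgh(profiles: Iterable[CGHProfile], path) -> None:
    frames = []
    for prof in profiles:
        frame = prof.probes.copy()
        frame.insert(0, "patient_id", prof.patient_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe-gene map and gene coordinates


def read_probe_gene_map(path) -> pd.DataFrame:
    """Two-column TSV (probe_id, gene_symbol); many-to-many allowed."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["probe_id", "gene_symbol"]:
        raise FormatError(
            f"{path}: expected columns probe_id, gene_symbol")
    if table.isna().any().any() or (table == "").any().any():
        raise FormatError(f"{path}: blank identifiers in probe-gene map")
    return table


def read_bed(path) -> pd.DataFrame:
    """Read gene coordinates from BED (0-based half-open) to 1-based inclusive.

    Returns a DataFrame with columns gene, chromosome, start, end.
    """
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        dtype={0: str, 3: str})
    if table.shape[1] < 4:
        raise FormatError(f"{path}: BED needs chrom, start, end, name columns")
    out = pd.DataFrame({
        "gene": table.iloc[:, 3],
        "chromosome": table.iloc[:, 0],
        "start": table.iloc[:, 1].astype(int) + 1,
        "end": table.iloc[:, 2].astype(int),
    })
    if (out["end"] < out["start"]).any():
        raise FormatError(f"{path}: empty or negative BED interval")
    return out


def write_gene_coords_bed(coords: pd.DataFrame, path) -> None:
    """Write a gene-coordinate table (1-based inclusive) as BED."""
    bed = pd.DataFrame({
        0: coords["chromosome"],
        1: coords["start"].astype(int) - 1,
        2: coords["end"].astype(int),
        3: coords["gene"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# packaged fixtures: the printed signature tables and literature gene sets


def _fixture_path(name: str):
    return resources.files("stromasig.fixtures").joinpath(name)


def load_signature_table(which: str) -> pd.DataFrame:
    """Printed signature tables as DataFrames.

    ``which`` is one of ``micro_over`` (42 genes up in microdissected
    tumors), ``macro_over`` (73 genes up in macrodissected tumors) or
    ``under`` (37 micro + 8 macro down-regulated genes, with a ``method``
    column).  Fold changes carry the signed convention (-25 means 25-fold
    lower in tumor).
    """
    names = {
        "micro_over": "table_micro_overexpressed.tsv",
        "macro_over": "table_macro_overexpressed.tsv",
        "under": "table_underexpressed.tsv",
    }
    if which not in names:
        raise KeyError(f"unknown signature table {which!r}")
    with resources.as_file(_fixture_path(names[which])) as p:
        return pd.read_csv(p, sep="\t", dtype={"gene": str})


def load_literature_sets() -> dict:
    """Literature gene sets partitioned by the method(s) that detected them.

    Keys like ``table5_over_both`` / ``table5_over_lcm_only`` /
    ``table5_over_macro_only`` and the ``under`` equivalents, plus the
    pooled ``literature_over`` and ``literature_under`` unions.
    """
    out = {}
    for fname in ("table5_overexpressed.gmt", "table5_underexpressed.gmt"):
        with resources.as_file(_fixture_path(fname)) as p:
            for gs in read_gene_sets(p):
                out[gs.name] = gs
    over = frozenset().union(*(out[k].members for k in out if "_over_" in k))
    under = frozenset().union(*(out[k].members for k in out if "_under_" in k))
    out["literature_over"] = GeneSet("literature_over", over)
    out["literature_under"] = GeneSet("literature_under", under)
    return out
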