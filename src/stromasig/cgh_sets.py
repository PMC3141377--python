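"""Copy-number aberration calling and gain/loss gene-set construction.

The segment caller is a documented stand-in for Agilent's proprietary
ADM-2: it takes maximal runs of consecutive same-chromosome probes whose
log2 ratios share one sign and exceed a seed threshold (0.25, half the
retention amplitude), then applies the retention filters used in the
study verbatim — at least 5 probes, mean absolute log2 ratio at least
0.5, at most 1,000,000 aberrations (largest first).  Precomputed
segments can be supplied downstream to bypass the caller entirely.

Gene-set membership follows the strict rule: a gene enters the gain set
when its per-patient log2 ratio exceeds +0.5 in at least one patient,
and the loss set when it falls below -0.5 in at least one patient; a
gene may belong to both (different patients).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_formats import CGHProfile, GeneSet

SEED_THRESHOLD = 0.25
MIN_PROBES = 5
MIN_AVG_ABS_LOG2 = 0.5
MAX_ABERRATIONS = 1_000_000


@dataclass(frozen=True)
class AberrationSegment:
    """A called gain/loss interval (1-based inclusive bp)."""

    patient_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    mean_log2: float

    @property
    def direction(self) -> str:
        return "gain" if self.mean_log2 > 0 else "loss"


def call_aberrations(profile: CGHProfile,
                     seed_threshold: float = SEED_THRESHOLD,
                     min_probes: int = MIN_PROBES,
                     min_avg_abs_log2: float = MIN_AVG_ABS_LOG2,
                     max_aberrations: int = MAX_ABERRATIONS) -> List[AberrationSegment]:
    """Call aberration segments from one probe-level profile.

    Segments are maximal runs of consecutive probes with same-sign log2
    ratios of magnitude >= ``seed_threshold``, retained when the run has
    >= ``min_probes`` probes and mean |log2| >= ``min_avg_abs_log2``.
    Returns at most ``max_aberrations`` segments, largest |mean| first.
    """
    segments: List[AberrationSegment] = []
    for chrom, grp in profile.probes.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        ratio = grp["log2_ratio"].to_numpy(dtype=float)
        state = np.where(ratio >= seed_threshold, 1,
                         np.where(ratio <= -seed_threshold, -1, 0))
        # run boundaries wherever the seed state changes
        edges = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [state.size]))
        for lo, hi in zip(starts, ends):
            if state[lo] == 0 or hi - lo < min_probes:
                continue
            mean = float(ratio[lo:hi].mean())
            if abs(mean) < min_avg_abs_log2:
                continue
            segments.append(AberrationSegment(
                patient_id=profile.patient_id, chromosome=str(chrom),
                start=int(pos[lo]), end=int(pos[hi - 1]),
                n_probes=int(hi - lo), mean_log2=mean))
    segments.sort(key=lambda s: (-abs(s.mean_log2), s.chromosome, s.start))
    return segments[:max_aberrations]


def _check_coords(gene_coords: pd.DataFrame) -> pd.DataFrame:
    need = {"gene", "chromosome", "start", "end"}
    missing = need - set(gene_coords.columns)
    if missing:
        raise AnalysisError(f"gene coordinate table lacks columns {sorted(missing)}")
    return gene_coords


def genes_in_segments(segments: Iterable[AberrationSegment],
                      gene_coords: pd.DataFrame) -> pd.DataFrame:
    """Map called segments to the genes they overlap (closed intervals).

    Returns a DataFrame with one row per (patient, direction, gene); a
    gene is included as soon as its interval shares >= 1 bp with a
    segment.  Chromosome names present in the segments but absent from
    the coordinate table raise an error listing the offenders.
    """
    gene_coords = _check_coords(gene_coords)
    segments = list(segments)
    seg_chroms = {s.chromosome for s in segments}
    known = set(gene_coords["chromosome"].astype(str))
    unknown = sorted(seg_chroms - known)
    if unknown:
        raise AnalysisError(
            f"segment chromosome(s) missing from gene coordinates: {unknown}")
    by_chrom = {str(c): g for c, g in gene_coords.groupby("chromosome")}
    rows = []
    for seg in segments:
        genes = by_chrom[seg.chromosome]
        hit = genes[(genes["start"] <= seg.end) & (genes["end"] >= seg.start)]
        for gene in hit["gene"]:
            rows.append({"patient_id": seg.patient_id,
                         "direction": seg.direction, "gene": gene,
                         "chromosome": seg.chromosome})
    frame = pd.DataFrame(rows, columns=["patient_id", "direction", "gene",
                                        "chromosome"])
    return frame.drop_duplicates(ignore_index=True)


def per_patient_gene_log2(profiles: Iterable[CGHProfile],
                          gene_coords: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-patient log2 ratio: mean of probes overlapping the gene.

    Genes with no overlapping probe in a patient are omitted for that
    patient.  Output columns: gene, patient, log2.
    """
    gene_coords = _check_coords(gene_coords)
    rows = []
    for prof in profiles:
        for chrom, probes in prof.probes.groupby("chromosome", sort=False):
            genes = gene_coords[gene_coords["chromosome"].astype(str) == str(chrom)]
            if genes.empty:
                continue
            pos = probes["position"].to_numpy()
            ratio = probes["log2_ratio"].to_numpy(dtype=float)
            lo = np.searchsorted(pos, genes["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, genes["end"].to_numpy(), side="right")
            for gene, a, b in zip(genes["gene"], lo, hi):
                if b > a:
                    rows.append({"gene": gene, "patient": prof.patient_id,
                                 "log2": float(ratio[a:b].mean())})
    return pd.DataFrame(rows, columns=["gene", "patient", "log2"])


def build_cn_genesets(per_patient_gene_log2: pd.DataFrame,
                      threshold: float = 0.5):
    """Gain/loss gene sets by the strict one-patient rule.

    Gain: log2 > threshold in at least one patient.  Loss: log2 <
    -threshold in at least one patient.  The boundary is strict, so a
    gene whose best patient sits exactly at the threshold is excluded.
    """
    table = per_patient_gene_log2
    if table.empty:
        raise AnalysisError("empty per-gene log2 table")
    need = {"gene", "log2"}
    if not need <= set(table.columns):
        raise AnalysisError("per-gene table needs columns gene, patient, log2")
    gain = frozenset(table.loc[table["log2"] > threshold, "gene"])
    loss = frozenset(table.loc[table["log2"] < -threshold, "gene"])
    return GeneSet("cn_gain", gain), GeneSet("cn_loss", loss)


def segments_to_frame(segments: Iterable[AberrationSegment]) -> pd.DataFrame:
    """SEG-like table (one row per called segment)."""
    return pd.DataFrame(
        [{"patient_id": s.patient_id, "chromosome": s.chromosome,
          "start": s.start, "end": s.end, "n_probes": s.n_probes,
          "mean_log2": s.mean_log2, "direction": s.direction}
         for s in segments],
        columns=["patient_id", "chromosome", "start", "end", "n_probes",
                 "mean_log2", "direction"])
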