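"""Orchestration of the full macro-vs-micro comparison.

Builds a cancer-vs-normal matrix for each dissection method (tumors of
that method plus the pooled 6-sample normal class), runs differential
expression and the LS test for every gene set against each method's
full gene universe, maps CGH profiles to gain/loss gene sets, computes
the per-patient cross-method Pearson correlation, and assembles one
report mirroring the structure of the emulated study's results.

One master seed deterministically spawns a child seed per (method,
gene-set) cell, so adding a gene set never perturbs the resampling
stream of any other cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cgh_sets import build_cn_genesets, per_patient_gene_log2
from .diffexp import univariate_de
from .errors import AnalysisError
from .io_formats import CGHProfile, ExpressionMatrix, GeneSet
from .ls_enrichment import (LSResult, child_seed, ls_pvalue, member_report)

METHODS = ("macro", "micro")


@dataclass
class CorrelationSummary:
    """Per-patient macro-vs-micro Pearson r with median and IQR."""

    per_patient: pd.Series
    median: float
    iqr: Tuple[float, float]


def cross_method_correlation(macro: ExpressionMatrix,
                             micro: ExpressionMatrix) -> CorrelationSummary:
    """Pearson r between each patient's macro and micro profile.

    Samples are linked through ``patient_id``; at least one linked pair
    and three shared genes are required.
    """
    if macro.patient_id is None or micro.patient_id is None:
        raise AnalysisError("both matrices need patient_id labels")
    shared = macro.values.index.intersection(micro.values.index)
    if len(shared) < 3:
        raise AnalysisError("need >= 3 shared genes for correlation")
    pairs = []
    micro_by_patient = {p: s for s, p in micro.patient_id.items()}
    for s_macro, patient in macro.patient_id.items():
        s_micro = micro_by_patient.get(patient)
        if s_micro is not None:
            pairs.append((patient, s_macro, s_micro))
    if not pairs:
        raise AnalysisError("no macro/micro sample pairs share a patient_id")
    rs = {}
    for patient, s_macro, s_micro in pairs:
        x = macro.values.loc[shared, s_macro].to_numpy()
        y = micro.values.loc[shared, s_micro].to_numpy()
        rs[patient] = float(np.corrcoef(x, y)[0, 1])
    per_patient = pd.Series(rs, name="pearson_r")
    q1, med, q3 = np.percentile(per_patient.to_numpy(), [25, 50, 75])
    return CorrelationSummary(per_patient, float(med), (float(q1), float(q3)))


@dataclass
class GridCell:
    """One (method, gene set) cell of the comparison grid."""

    method: str
    set_name: str
    result: Optional[LSResult]
    reason: Optional[str] = None   # why the cell is NA, when it is

    @property
    def ok(self) -> bool:
        return self.result is not None


@dataclass
class ComparisonReport:
    """Grid of LS results plus correlation and member partitions."""

    cells: List[GridCell]
    correlation: Optional[CorrelationSummary]
    members: Dict[str, pd.DataFrame]
    de: Dict[str, pd.DataFrame]
    metadata: dict

    def cell(self, method: str, set_name: str) -> GridCell:
        for c in self.cells:
            if c.method == method and c.set_name == set_name:
                return c
        raise KeyError((method, set_name))

    def grid(self) -> pd.DataFrame:
        """Long-format table, one row per grid cell."""
        rows = []
        for c in self.cells:
            row = {"set": c.set_name, "method": c.method}
            if c.ok:
                r = c.result
                row.update(N=r.n, ls_statistic=r.ls_statistic, R=r.r,
                           ls_p=r.ls_p, display_p=r.display_p,
                           significant=r.significant, seed=r.seed)
            else:
                row.update(N=0, ls_statistic=np.nan, R=0, ls_p=np.nan,
                           display_p=f"NA ({c.reason})", significant=False,
                           seed=-1)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = ["Gene-set enrichment by dissection method (LS resampling test)",
                 ""]
        for c in self.cells:
            if c.ok:
                r = c.result
                flag = "significant" if r.significant else "not significant"
                lines.append(
                    f"  {c.set_name:<18} {c.method:<6} N={r.n:<5} "
                    f"LS={r.ls_statistic:6.3f}  LS P {r.display_p} ({flag})")
            else:
                lines.append(f"  {c.set_name:<18} {c.method:<6} NA: {c.reason}")
        if self.correlation is not None:
            q1, q3 = self.correlation.iqr
            lines += ["", f"Cross-method Pearson r: median "
                          f"{self.correlation.median:.2f} "
                          f"(interquartile range, {q1:.2f}-{q3:.2f})"]
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        import json
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.grid().to_csv(out / "ls_grid.tsv", sep="\t", index=False)
        for name, frame in self.members.items():
            frame.to_csv(out / f"members_{name}.tsv", sep="\t")
        if self.correlation is not None:
            self.correlation.per_patient.to_csv(
                out / "cross_method_correlation.tsv", sep="\t",
                header=["pearson_r"])
        (out / "summary.txt").write_text(self.summary_text() + "\n",
                                         encoding="utf-8")
        (out / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str),
            encoding="utf-8")


def run_comparison(macro: ExpressionMatrix, micro: ExpressionMatrix,
                   normals: ExpressionMatrix,
                   gene_sets: Iterable[GeneSet] = (),
                   cgh: Optional[Iterable[CGHProfile]] = None,
                   gene_coords: Optional[pd.DataFrame] = None,
                   cn_sets: Optional[Tuple[GeneSet, GeneSet]] = None,
                   R: int = 10_000, seed: int = 0, test: str = "welch",
                   cn_threshold: float = 0.5, member_alpha: float = 0.05,
                   pooled_normals: bool = True,
                   correlate: bool = True) -> ComparisonReport:
    """Run the full grid: DE per method, LS test per (method, set) cell.

    Gene sets come from three sources: ``gene_sets`` (literature-style
    sets), precomputed ``cn_sets``, or raw ``cgh`` profiles plus
    ``gene_coords`` (per-gene log2 = mean of overlapping probes, then
    the strict one-patient gain/loss rule at ``cn_threshold``).  With
    ``pooled_normals`` (the study's design) the same 6 normals serve
    both methods; otherwise each method uses its method-matched normals.
    """
    sets: List[GeneSet] = list(gene_sets)
    if cn_sets is not None:
        sets = [s for s in cn_sets if len(s)] + sets
    elif cgh is not None:
        if gene_coords is None:
            raise AnalysisError("cgh profiles need gene_coords to build sets")
        table = per_patient_gene_log2(cgh, gene_coords)
        gain, loss = build_cn_genesets(table, threshold=cn_threshold)
        sets = [s for s in (gain, loss) if len(s)] + sets
    if not sets:
        raise AnalysisError("nothing to test: no gene sets from any source")

    tumor = {"macro": macro, "micro": micro}
    de = {}
    for method in METHODS:
        if pooled_normals:
            norm = normals
        else:
            keep = normals.sample_method == method
            norm = normals.select_samples(normals.values.columns[keep])
        combined = ExpressionMatrix.combine(tumor[method], norm)
        de[method] = univariate_de(combined, test=test)

    cells: List[GridCell] = []
    for gs in sets:
        for method in METHODS:
            cs = child_seed(seed, method, gs.name)
            try:
                res = ls_pvalue(gs, de[method]["p_value"], R=R, seed=cs)
                cells.append(GridCell(method, gs.name, res))
            except AnalysisError as exc:
                cells.append(GridCell(method, gs.name, None, str(exc)))

    members = {gs.name: member_report(gs, de["macro"], de["micro"],
                                      alpha=member_alpha)
               for gs in sets}
    corr = cross_method_correlation(macro, micro) if correlate else None
    metadata = {
        "version": _version, "seed": int(seed), "R": int(R), "test": test,
        "cn_threshold": cn_threshold, "member_alpha": member_alpha,
        "pooled_normals": pooled_normals,
        "sets": {gs.name: len(gs) for gs in sets},
        "n_tumor_macro": macro.n_samples, "n_tumor_micro": micro.n_samples,
        "n_normal": normals.n_samples,
    }
    return ComparisonReport(cells, corr, members, de, metadata)
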