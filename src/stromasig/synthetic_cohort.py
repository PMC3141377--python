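"""Seeded synthetic macro/micro paired gastric-cancer cohorts.

The generator emulates the statistical structure of a paired
dissection-comparison study: the same tumors profiled twice, once by
histologic macrodissection (high yield, substantial stromal admixture)
and once by laser-capture microdissection (near-pure epithelium, but an
extra amplification round that silences a fraction of transcripts).

Generative model, per gene g and tumor t (all on the log2 scale except
where noted):

* epithelial level  E(g,t) = baseline(g) + z(g,t) * effect(g)
                             + dose_coefficient * segment_log2(g,t)
                             + noise,
  where z(g,t) is a Bernoulli penetrance indicator modelling intra-tumor
  heterogeneity (not every tumor deregulates every signature gene) and
  the dose term applies only to copy-number-driven genes in patients
  carrying the planted segment;
* stromal level     S(g,t) = baseline(g) + stromal_boost(g) + noise,
  boost nonzero only for stromal-specific transcripts (collagens and
  friends);
* macro sample      log2( purity_macro(t) * 2^E + (1-purity_macro(t)) * 2^S ),
  i.e. RNA mixes on the linear intensity scale;
* micro sample      the same mixture at purity_micro, then each
  (gene, sample) cell independently collapses to a floor value with
  probability dropout_rate (amplification transcript loss);
* normal samples    baseline(g) + noise.

Macro purity is drawn per patient from a Beta distribution matched to
the post-dissection figures of the emulated study (median 0.60, IQR
0.60-0.725); CGH profiles contain the planted segments plus flat probe
noise elsewhere.  Identical config + seed gives bit-identical output.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from typing import List, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import CGHProfile, ExpressionMatrix, GeneSet

ROLES = ("epithelial_up", "epithelial_down", "stromal_specific", "housekeeping")


@dataclass
class CohortConfig:
    """Study-design and generative parameters of the synthetic cohort.

    Defaults mirror the emulated study: 20 tumors profiled by both
    methods, 6 normals (3 per method), macro purity with median 0.60 and
    IQR 0.60-0.725, near-pure LCM (0.95), 30% amplification dropout, and
    a 2,000-gene desk-scale genome.  Effect magnitudes span 2- to
    32-fold, matching the printed signature fold-change range.
    """

    n_tumor: int = 20
    n_normal: int = 6
    n_genes: int = 2000
    purity_macro_median: float = 0.60
    purity_macro_iqr: Tuple[float, float] = (0.60, 0.725)
    purity_micro: float = 0.95
    dropout_rate: float = 0.30
    dropout_floor_log2: float = 0.0
    noise_sd_log2: float = 1.25
    cn_dose_coefficient: float = 1.0
    # role composition
    n_epithelial_up: int = 60
    n_epithelial_down: int = 60
    n_stromal: int = 150
    n_cn_gain: int = 30
    n_cn_loss: int = 30
    amplicon_genes: int = 10          # genes per planted segment
    carrier_prob: float = 0.30        # patient carries a given amplicon
    effect_log2_low: float = 1.0
    effect_log2_high: float = 5.0
    stromal_boost_low: float = 1.0
    stromal_boost_high: float = 4.0
    effect_penetrance: float = 0.5    # fraction of tumors deregulating a gene
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    segment_abs_log2_low: float = 0.55
    segment_abs_log2_high: float = 1.5
    probes_per_gene: int = 5
    cgh_noise_sd: float = 0.10
    n_chromosomes: int = 10
    seed: int = 0

    def validate(self) -> None:
        numeric = [self.purity_macro_median, *self.purity_macro_iqr,
                   self.purity_micro, self.dropout_rate, self.carrier_prob,
                   self.effect_penetrance]
        for frac in numeric:
            if not np.isfinite(frac) or not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction out of [0, 1]: {frac!r}")
        for val in (self.noise_sd_log2, self.cgh_noise_sd,
                    self.baseline_sd_log2):
            if not np.isfinite(val) or val < 0:
                raise ConfigError(f"negative or non-finite SD: {val!r}")
        if not np.isfinite(self.cn_dose_coefficient):
            raise ConfigError("cn_dose_coefficient must be finite")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ConfigError("need at least 2 tumors and 2 normals")
        n_effect = self.n_epithelial_up + self.n_epithelial_down + self.n_stromal
        if n_effect > self.n_genes:
            raise ConfigError("role counts exceed n_genes")
        if self.n_cn_gain > self.n_epithelial_up or self.n_cn_loss > self.n_epithelial_down:
            raise ConfigError("cn-driven genes must fit inside the effect roles")
        if self.amplicon_genes < 1 or self.probes_per_gene < 1:
            raise ConfigError("amplicon_genes and probes_per_gene must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    roles: pd.DataFrame          # gene, role, cn_driven, effect_log2, stromal_boost, chromosome, start, end
    purity: pd.DataFrame         # patient_id, purity_macro, purity_micro
    segments: pd.DataFrame       # patient_id, chromosome, start, end, log2, n_genes
    dropout_mask: pd.DataFrame   # genes x micro tumor samples, bool
    config: CohortConfig

    @property
    def gene_coords(self) -> pd.DataFrame:
        return self.roles[["gene", "chromosome", "start", "end"]]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "roles": self.roles.to_dict(orient="list"),
            "purity": self.purity.to_dict(orient="list"),
            "segments": self.segments.to_dict(orient="list"),
            "dropout_mask": {
                "genes": self.dropout_mask.index.tolist(),
                "samples": self.dropout_mask.columns.tolist(),
                "floored": [[int(g), int(s)] for g, s in
                            zip(*np.nonzero(self.dropout_mask.to_numpy()))],
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg_fields = {f.name for f in fields(CohortConfig)}
        cfg = payload["config"]
        cfg["purity_macro_iqr"] = tuple(cfg["purity_macro_iqr"])
        config = CohortConfig(**{k: v for k, v in cfg.items() if k in cfg_fields})
        dm = payload["dropout_mask"]
        mask = np.zeros((len(dm["genes"]), len(dm["samples"])), dtype=bool)
        for g, s in dm["floored"]:
            mask[g, s] = True
        return cls(
            roles=pd.DataFrame(payload["roles"]),
            purity=pd.DataFrame(payload["purity"]),
            segments=pd.DataFrame(payload["segments"]),
            dropout_mask=pd.DataFrame(mask, index=dm["genes"],
                                      columns=dm["samples"]),
            config=config)


@dataclass
class Cohort:
    """Everything one simulation run produces."""

    macro: ExpressionMatrix
    micro: ExpressionMatrix
    normals: ExpressionMatrix
    cgh: List[CGHProfile]
    truth: SyntheticTruth

    def __iter__(self):
        return iter((self.macro, self.micro, self.normals, self.cgh, self.truth))


GENE_LENGTH = 100_000
GENE_SPACING = 150_000


def _beta_params(median: float, iqr: Tuple[float, float]) -> Tuple[float, float]:
    """Beta(a, b) approximately matching a median and interquartile range."""
    q1, q3 = iqr
    mean = float(np.clip((q1 + median + q3) / 3.0, 1e-3, 1 - 1e-3))
    sd = max((q3 - q1) / 1.349, 0.02)
    var = min(sd ** 2, mean * (1 - mean) * 0.99)
    kappa = mean * (1 - mean) / var - 1.0
    return mean * kappa, (1 - mean) * kappa


def _gene_layout(cfg: CohortConfig) -> pd.DataFrame:
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    chroms, starts = [], []
    for i in range(cfg.n_genes):
        chroms.append(str(i // per_chrom + 1))
        starts.append(1 + (i % per_chrom) * GENE_SPACING)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    return pd.DataFrame({
        "gene": genes, "chromosome": chroms, "start": starts,
        "end": [s + GENE_LENGTH - 1 for s in starts]})


def simulate_cohort(config: CohortConfig | None = None, seed=None) -> Cohort:
    """Simulate one paired macro/micro cohort under the generative model.

    Returns macro, micro and normal expression matrices, per-patient CGH
    profiles, and the ground truth needed for recovery tests.
    """
    cfg = config if config is not None else CohortConfig()
    if seed is not None:
        cfg = CohortConfig(**{**asdict(cfg), "seed": int(seed)})
        cfg.purity_macro_iqr = tuple(cfg.purity_macro_iqr)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, T, Nn = cfg.n_genes, cfg.n_tumor, cfg.n_normal

    layout = _gene_layout(cfg)
    baseline = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, G)
    baseline = np.clip(baseline, 4.0, 14.0)

    # --- roles -----------------------------------------------------------
    role = np.array(["housekeeping"] * G, dtype=object)
    cn_driven = np.zeros(G, dtype=bool)
    # contiguous amplicon blocks for copy-number-driven genes
    n_blocks_total = G // cfg.amplicon_genes
    n_gain_blocks = math.ceil(cfg.n_cn_gain / cfg.amplicon_genes)
    n_loss_blocks = math.ceil(cfg.n_cn_loss / cfg.amplicon_genes)
    blocks = rng.choice(n_blocks_total, size=n_gain_blocks + n_loss_blocks,
                        replace=False)
    gain_idx, loss_idx = [], []
    for k, blk in enumerate(blocks):
        idx = list(range(blk * cfg.amplicon_genes,
                         (blk + 1) * cfg.amplicon_genes))
        (gain_idx if k < n_gain_blocks else loss_idx).extend(idx)
    gain_idx = np.array(gain_idx[:cfg.n_cn_gain], dtype=int)
    loss_idx = np.array(loss_idx[:cfg.n_cn_loss], dtype=int)
    role[gain_idx] = "epithelial_up"
    role[loss_idx] = "epithelial_down"
    cn_driven[gain_idx] = True
    cn_driven[loss_idx] = True

    free = np.flatnonzero(role == "housekeeping")
    n_extra_up = cfg.n_epithelial_up - cfg.n_cn_gain
    n_extra_down = cfg.n_epithelial_down - cfg.n_cn_loss
    picks = rng.choice(free, size=n_extra_up + n_extra_down + cfg.n_stromal,
                       replace=False)
    role[picks[:n_extra_up]] = "epithelial_up"
    role[picks[n_extra_up:n_extra_up + n_extra_down]] = "epithelial_down"
    role[picks[n_extra_up + n_extra_down:]] = "stromal_specific"

    effect = np.zeros(G)
    is_up = role == "epithelial_up"
    is_down = role == "epithelial_down"
    effect[is_up] = rng.uniform(cfg.effect_log2_low, cfg.effect_log2_high,
                                is_up.sum())
    effect[is_down] = -rng.uniform(cfg.effect_log2_low, cfg.effect_log2_high,
                                   is_down.sum())
    boost = np.zeros(G)
    is_stromal = role == "stromal_specific"
    boost[is_stromal] = rng.uniform(cfg.stromal_boost_low,
                                    cfg.stromal_boost_high, is_stromal.sum())

    # --- copy-number carriers -------------------------------------------
    amplicon_of = {}
    for k, blk in enumerate(blocks):
        sign = 1.0 if k < n_gain_blocks else -1.0
        idx = [i for i in range(blk * cfg.amplicon_genes,
                                (blk + 1) * cfg.amplicon_genes)
               if cn_driven[i]]
        if idx:
            amplicon_of[k] = (sign, np.array(idx))
    carriers = rng.random((len(amplicon_of), T)) < cfg.carrier_prob
    amp_log2 = rng.uniform(cfg.segment_abs_log2_low, cfg.segment_abs_log2_high,
                           (len(amplicon_of), T))
    seg_log2 = np.zeros((G, T))
    seg_rows = []
    patients = [f"P{t + 1:02d}" for t in range(T)]
    for row, (k, (sign, idx)) in enumerate(amplicon_of.items()):
        for t in range(T):
            if carriers[row, t]:
                value = sign * amp_log2[row, t]
                seg_log2[idx, t] = value
                seg_rows.append({
                    "patient_id": patients[t],
                    "chromosome": layout.loc[idx[0], "chromosome"],
                    "start": int(layout.loc[idx[0], "start"]),
                    "end": int(layout.loc[idx[-1], "end"]),
                    "log2": float(value), "n_genes": len(idx)})

    # --- expression ------------------------------------------------------
    sd = cfg.noise_sd_log2
    is_effect = is_up | is_down
    pen = np.ones((G, T))
    pen[is_effect] = rng.random((int(is_effect.sum()), T)) < cfg.effect_penetrance
    E = (baseline[:, None] + pen * effect[:, None]
         + cfg.cn_dose_coefficient * seg_log2
         + rng.normal(0.0, sd, (G, T)))
    S = baseline[:, None] + boost[:, None] + rng.normal(0.0, sd, (G, T))

    purity = rng.beta(*_beta_params(cfg.purity_macro_median,
                                    tuple(cfg.purity_macro_iqr)), T)
    # exact degenerate purities are honored (mixture collapses cleanly)
    if cfg.purity_macro_median in (0.0, 1.0) and \
            tuple(cfg.purity_macro_iqr) == (cfg.purity_macro_median,) * 2:
        purity = np.full(T, cfg.purity_macro_median)

    def mix(pur_vec: np.ndarray) -> np.ndarray:
        return np.log2(pur_vec[None, :] * np.exp2(E)
                       + (1.0 - pur_vec[None, :]) * np.exp2(S))

    macro_vals = mix(purity)
    micro_vals = mix(np.full(T, cfg.purity_micro))
    mask = rng.random((G, T)) < cfg.dropout_rate
    micro_vals = np.where(mask, cfg.dropout_floor_log2, micro_vals)

    normal_vals = baseline[:, None] + rng.normal(0.0, sd, (G, Nn))

    genes = layout["gene"].tolist()
    macro = ExpressionMatrix(
        pd.DataFrame(macro_vals, index=genes,
                     columns=[f"{p}_macro" for p in patients]),
        "cancer", "macro", patients)
    micro = ExpressionMatrix(
        pd.DataFrame(micro_vals, index=genes,
                     columns=[f"{p}_micro" for p in patients]),
        "cancer", "micro", patients)
    half = Nn // 2
    volunteers = [f"V{i + 1}" for i in range(Nn)]
    n_methods = ["macro"] * half + ["micro"] * (Nn - half)
    normals = ExpressionMatrix(
        pd.DataFrame(normal_vals, index=genes,
                     columns=[f"{v}_{m}" for v, m in zip(volunteers, n_methods)]),
        "normal", n_methods, volunteers)

    # --- CGH profiles ----------------------------------------------------
    probes_per_gene = cfg.probes_per_gene
    step = GENE_LENGTH // probes_per_gene
    probe_pos = (layout["start"].to_numpy()[:, None]
                 + np.arange(probes_per_gene)[None, :] * step).ravel()
    probe_chrom = np.repeat(layout["chromosome"].to_numpy(), probes_per_gene)
    cgh = []
    for t, pid in enumerate(patients):
        ratio = (np.repeat(seg_log2[:, t], probes_per_gene)
                 + rng.normal(0.0, cfg.cgh_noise_sd, G * probes_per_gene))
        cgh.append(CGHProfile(pid, pd.DataFrame({
            "chromosome": probe_chrom, "position": probe_pos,
            "log2_ratio": ratio})))

    roles = layout.copy()
    roles.insert(1, "role", role)
    roles.insert(2, "cn_driven", cn_driven)
    roles.insert(3, "effect_log2", effect)
    roles.insert(4, "stromal_boost", boost)
    truth = SyntheticTruth(
        roles=roles,
        purity=pd.DataFrame({"patient_id": patients, "purity_macro": purity,
                             "purity_micro": cfg.purity_micro}),
        segments=pd.DataFrame(
            seg_rows, columns=["patient_id", "chromosome", "start", "end",
                               "log2", "n_genes"]),
        dropout_mask=pd.DataFrame(mask, index=genes,
                                  columns=micro.sample_ids),
        config=cfg)
    return Cohort(macro, micro, normals, cgh, truth)


def planted_sets(truth: SyntheticTruth) -> List[GeneSet]:
    """Ground-truth gene sets mirroring the study's four comparisons.

    ``cn_gain`` / ``cn_loss`` (copy-number-driven genes) and
    ``epithelial_up`` / ``epithelial_down`` (the literature-signature
    analogs).  Empty sets are omitted, not emitted.
    """
    roles = truth.roles
    out = []
    for name, mask in (
            ("cn_gain", (roles["role"] == "epithelial_up") & roles["cn_driven"]),
            ("cn_loss", (roles["role"] == "epithelial_down") & roles["cn_driven"]),
            ("epithelial_up", roles["role"] == "epithelial_up"),
            ("epithelial_down", roles["role"] == "epithelial_down")):
        members = frozenset(roles.loc[mask, "gene"])
        if members:
            out.append(GeneSet(name, members))
    return out
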