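"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emits a toy genome, non-overlapping regulatory elements,
one informative PWM per TF, a ground-truth TF-CRM-TG network with the
TF's motif planted inside each truth CRM element, an element-to-gene
linear model, a panel of paired expression/accessibility samples, noisy
replicate networks sharing the latent truth, and SNP panels with causal
variants placed inside CRMs.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenomeIndex,
    GenomicInterval,
    PWM,
    SnpRecord,
    ValidationError,
)
from .netbuild import InteractionModel, PairedSample, RegulatoryElement
from .networks import ConsensusNetwork, ReplicateNetwork, SolverDiagnostics, Triplet

_BASES = "ACGT"


@dataclass
class TruthConfig:
    """Generator knobs; defaults give a full pipeline run in minutes."""

    n_chroms: int = 2
    chrom_length: int = 100_000
    n_tfs: int = 20
    n_tgs: int = 100
    n_res: int = 300
    re_width: int = 200
    motif_width: int = 10
    edge_density: float = 0.05
    n_replicates: int = 6
    sigma_s: float | None = None  # None -> 0.2 * mean truth score
    crm_jitter: int = 20
    sigma_e: float = 0.1
    n_panel: int = 148
    window: int = 10_000
    pwm_threshold_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length, self.n_tfs, self.n_tgs,
            self.n_res, self.re_width, self.motif_width, self.n_replicates,
            self.n_panel, self.window,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be >= 1")
        if not (0 < self.edge_density <= 1):
            raise ValidationError("edge_density must be in (0, 1]")
        if (self.sigma_s is not None and self.sigma_s < 0) or self.sigma_e < 0:
            raise ValidationError("noise scales must be >= 0")
        if self.crm_jitter < 0:
            raise ValidationError("crm_jitter must be >= 0")


@dataclass
class GroundTruth:
    config: TruthConfig
    genome: dict[str, str]
    genome_index: GenomeIndex
    res: list[RegulatoryElement]
    pwms: list[PWM]
    pwm_counts: dict[str, np.ndarray]
    tf_ids: list[str]
    tg_ids: list[str]
    tss: dict[str, tuple[str, int]]
    candidates: dict[str, list[int]]
    model: InteractionModel  # the true I*
    network: ConsensusNetwork  # truth triplets (S*, C*)
    tf_expression: dict[str, float]
    panel_expr: ExpressionMatrix
    panel_access: np.ndarray  # n_res x n_panel

    @property
    def truth_edges(self) -> set[tuple[str, str]]:
        return self.network.edges()


def _random_genome(rng: np.random.Generator, cfg: TruthConfig) -> dict[str, list[str]]:
    return {
        f"chr{c + 1}": [
            _BASES[b] for b in rng.integers(0, 4, size=cfg.chrom_length)
        ]
        for c in range(cfg.n_chroms)
    }


def _place_res(rng: np.random.Generator, cfg: TruthConfig) -> list[GenomicInterval]:
    gap = 50
    pitch = cfg.re_width + gap
    slots = [
        (f"chr{c + 1}", s * pitch)
        for c in range(cfg.n_chroms)
        for s in range(cfg.chrom_length // pitch)
    ]
    if cfg.n_res > len(slots):
        raise ValidationError(
            f"cannot place {cfg.n_res} non-overlapping REs of width "
            f"{cfg.re_width} in this genome"
        )
    chosen = rng.choice(len(slots), size=cfg.n_res, replace=False)
    intervals = []
    for idx in sorted(chosen):
        chrom, slot_start = slots[idx]
        start = slot_start + int(rng.integers(0, gap))
        intervals.append(
            GenomicInterval(chrom, start, start + cfg.re_width, id=f"re{idx}")
        )
    return intervals


def _distinct_consensi(rng: np.random.Generator, n: int, width: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(_BASES[b] for b in rng.integers(0, 4, size=width))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def generate_truth(config: TruthConfig | None = None) -> GroundTruth:
    """Build a complete seeded ground-truth instance.

    Each truth edge (i, j) owns a CRM of one or two candidate elements of
    target j with TF i's consensus planted inside, a log-normal latent
    strength S*, and positive I* weights on exactly its CRM elements.
    """
    cfg = config or TruthConfig()
    rng = np.random.default_rng(cfg.seed)

    genome = _random_genome(rng, cfg)
    genome_index = GenomeIndex({c: cfg.chrom_length for c in genome})
    intervals = _place_res(rng, cfg)

    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    tg_ids = [f"G{j + 1:03d}" for j in range(cfg.n_tgs)]

    consensi = _distinct_consensi(rng, cfg.n_tfs, cfg.motif_width)
    pwms, pwm_counts = [], {}
    for tf, consensus in zip(tf_ids, consensi):
        counts = np.zeros((4, cfg.motif_width))
        for pos, base in enumerate(consensus):
            counts[_BASES.index(base), pos] = 12.0
        pwm_counts[tf] = counts
        pwms.append(
            PWM.from_counts(tf, counts, threshold_frac=cfg.pwm_threshold_frac)
        )

    # TSS near a random element so every gene has candidate REs
    tss: dict[str, tuple[str, int]] = {}
    for tg in tg_ids:
        anchor = intervals[int(rng.integers(len(intervals)))]
        pos = int(
            np.clip(
                anchor.start + rng.integers(-cfg.window // 2, cfg.window // 2 + 1),
                0,
                cfg.chrom_length - 1,
            )
        )
        tss[tg] = (anchor.chrom, pos)
    candidates = {
        tg: [
            k
            for k, iv in enumerate(intervals)
            if iv.chrom == tss[tg][0]
            and iv.start < tss[tg][1] + cfg.window
            and iv.end > tss[tg][1] - cfg.window
        ]
        for tg in tg_ids
    }

    # truth edges with planted motifs; per-RE motif slots avoid overwrites
    slot_pitch = cfg.motif_width + 2
    n_slots = cfg.re_width // slot_pitch
    free_slots: dict[int, list[int]] = {
        k: list(range(n_slots)) for k in range(len(intervals))
    }
    planted: dict[int, set[int]] = {}  # RE index -> TF indices with motif inside
    model_weights: dict[str, dict[int, float]] = {tg: {} for tg in tg_ids}
    for i, tf in enumerate(tf_ids):
        for j, tg in enumerate(tg_ids):
            if rng.random() >= cfg.edge_density:
                continue
            cand = candidates[tg]
            if not cand:
                continue
            n_crm = 2 if (len(cand) >= 2 and rng.random() < 0.3) else 1
            picks = rng.choice(cand, size=min(n_crm, len(cand)), replace=False)
            for k in picks:
                k = int(k)
                if i not in planted.get(k, set()):
                    if not free_slots[k]:
                        continue
                    slot = free_slots[k].pop(int(rng.integers(len(free_slots[k]))))
                    iv = intervals[k]
                    offset = iv.start + slot * slot_pitch + 1
                    genome[iv.chrom][offset : offset + cfg.motif_width] = list(
                        consensi[i]
                    )
                    planted.setdefault(k, set()).add(i)
                if k not in model_weights[tg]:
                    model_weights[tg][k] = float(rng.uniform(0.5, 1.5))

    # The truth network is the closure of the implied relation: TF i
    # regulates gene j exactly when some candidate element of j both hosts
    # i's motif and carries positive weight on j.  Planting alone would
    # understate the truth wherever genes share elements.
    triplets: list[Triplet] = []
    for j, tg in enumerate(tg_ids):
        for i, tf in enumerate(tf_ids):
            crm = [
                intervals[k]
                for k in candidates[tg]
                if model_weights[tg].get(k, 0.0) > 0 and i in planted.get(k, set())
            ]
            if crm:
                score = float(rng.lognormal(0.0, 0.5))
                triplets.append(Triplet(tf, tg, score, tuple(crm)))

    genome_str = {c: "".join(seq) for c, seq in genome.items()}
    base_access = rng.lognormal(0.0, 0.5, size=cfg.n_res)
    res = [
        RegulatoryElement(
            iv,
            float(base_access[k]),
            genome_str[iv.chrom][iv.start : iv.end],
        )
        for k, iv in enumerate(intervals)
    ]

    intercepts = {tg: float(rng.uniform(0.0, 0.2)) for tg in tg_ids}
    model = InteractionModel(
        candidates={tg: list(c) for tg, c in candidates.items()},
        weights={
            tg: np.array(
                [model_weights[tg].get(k, 0.0) for k in candidates[tg]]
            )
            for tg in tg_ids
        },
        intercepts=intercepts,
    )

    # paired panel: accessibility varies log-normally around the base level,
    # gene expression follows the linear model plus Gaussian noise, and TF
    # expression tracks the mean expression of its truth targets
    panel_samples = [f"P{s + 1:03d}" for s in range(cfg.n_panel)]
    panel_access = base_access[:, None] * rng.lognormal(
        0.0, 0.3, size=(cfg.n_res, cfg.n_panel)
    )
    tg_panel = np.zeros((cfg.n_tgs, cfg.n_panel))
    for j, tg in enumerate(tg_ids):
        weights = model.weight_vector(tg, cfg.n_res)
        tg_panel[j] = (
            intercepts[tg]
            + weights @ panel_access
            + rng.normal(0.0, cfg.sigma_e, size=cfg.n_panel)
        )
    tg_panel = np.clip(tg_panel, 0.0, None)

    targets_of = {
        tf: [t.tg for t in triplets if t.tf == tf] for tf in tf_ids
    }
    tf_panel = np.zeros((cfg.n_tfs, cfg.n_panel))
    tg_index = {tg: j for j, tg in enumerate(tg_ids)}
    for i, tf in enumerate(tf_ids):
        if targets_of[tf]:
            rows = [tg_index[tg] for tg in targets_of[tf]]
            signal = tg_panel[rows].mean(axis=0)
        else:
            signal = np.zeros(cfg.n_panel)
        tf_panel[i] = np.clip(
            signal + rng.normal(0.5, 0.3, size=cfg.n_panel), 0.0, None
        )

    panel_expr = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([tf_panel, tg_panel]),
            index=tf_ids + tg_ids,
            columns=panel_samples,
        )
    )
    tf_expression = {
        tf: float(max(tf_panel[i].mean(), 0.1)) for i, tf in enumerate(tf_ids)
    }

    return GroundTruth(
        config=cfg,
        genome=genome_str,
        genome_index=genome_index,
        res=res,
        pwms=pwms,
        pwm_counts=pwm_counts,
        tf_ids=tf_ids,
        tg_ids=tg_ids,
        tss=tss,
        candidates=candidates,
        model=model,
        network=ConsensusNetwork(triplets, SolverDiagnostics(0, 0.0, 0.0, True)),
        tf_expression=tf_expression,
        panel_expr=panel_expr,
        panel_access=panel_access,
    )


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def _jitter_interval(
    iv: GenomicInterval,
    jitter: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> GenomicInterval:
    if jitter == 0:
        return iv
    start = int(np.clip(iv.start + rng.integers(-jitter, jitter + 1), 0, chrom_len - 1))
    end = int(np.clip(iv.end + rng.integers(-jitter, jitter + 1), 1, chrom_len))
    if start >= end:
        return iv
    return GenomicInterval(iv.chrom, start, end)


def simulate_replicates(
    truth: GroundTruth,
    n_replicates: int | None = None,
    sigma_s: float | None = None,
    crm_jitter: int | None = None,
    sigma_e: float | None = None,
    seed: int = 0,
) -> tuple[list[ReplicateNetwork], list[PairedSample]]:
    """Draw noisy replicates around the latent truth.

    Network level: S^r = S* + N(0, sigma_s) on every TF-TG pair, clamped at
    zero; positive pairs become triplets whose CRMs are the truth CRMs with
    endpoints jittered (truth edges) or one random candidate element
    (spurious pairs).  Data level: per-replicate accessibility and
    expression regenerated from the linear model with noise.
    """
    cfg = truth.config
    R = n_replicates if n_replicates is not None else cfg.n_replicates
    truth_scores = [t.score for t in truth.network]
    mean_score = float(np.mean(truth_scores)) if truth_scores else 1.0
    if sigma_s is None:
        sigma_s = cfg.sigma_s if cfg.sigma_s is not None else 0.2 * mean_score
    jitter = crm_jitter if crm_jitter is not None else cfg.crm_jitter
    sig_e = sigma_e if sigma_e is not None else cfg.sigma_e
    rng = np.random.default_rng(seed)

    S_star = np.zeros((cfg.n_tfs, cfg.n_tgs))
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}
    tg_index = {tg: j for j, tg in enumerate(truth.tg_ids)}
    for t in truth.network:
        S_star[tf_index[t.tf], tg_index[t.tg]] = t.score

    # Spurious pairs keep one decoy candidate element as their CRM.  The
    # decoy is drawn once per pair, not per replicate: replicate CRMs stem
    # from the same candidate structure (D_j and motif content), so
    # replicates disagree by jitter, not by unrelated elements.
    decoy: dict[tuple[str, str], GenomicInterval] = {}
    for tf in truth.tf_ids:
        for tg in truth.tg_ids:
            if (tf, tg) in truth.network:
                continue
            cand = truth.candidates.get(tg, [])
            if cand:
                decoy[(tf, tg)] = truth.res[
                    cand[int(rng.integers(len(cand)))]
                ].interval

    networks: list[ReplicateNetwork] = []
    samples: list[PairedSample] = []
    for r in range(R):
        S_r = np.clip(
            S_star + rng.normal(0.0, sigma_s, size=S_star.shape), 0.0, None
        )
        triplets = []
        for i, tf in enumerate(truth.tf_ids):
            for j, tg in enumerate(truth.tg_ids):
                if S_r[i, j] <= 0:
                    continue
                edge = (tf, tg)
                if edge in truth.network:
                    crm = tuple(
                        _jitter_interval(
                            iv, jitter, truth.genome_index[iv.chrom], rng
                        )
                        for iv in truth.network[edge].crm
                    )
                else:
                    if edge not in decoy:
                        continue
                    crm = (
                        _jitter_interval(
                            decoy[edge], jitter,
                            truth.genome_index[decoy[edge].chrom], rng,
                        ),
                    )
                triplets.append(Triplet(tf, tg, float(S_r[i, j]), crm))
        networks.append(
            ReplicateNetwork(
                f"rep{r + 1}", triplets, weight=1.0,
                n_tfs=cfg.n_tfs, n_tgs=cfg.n_tgs,
            )
        )

        access = np.array([re_.accessibility for re_ in truth.res]) * rng.lognormal(
            0.0, 0.2, size=cfg.n_res
        )
        expression: dict[str, float] = {}
        for tg in truth.tg_ids:
            weights = truth.model.weight_vector(tg, cfg.n_res)
            value = (
                truth.model.intercepts[tg]
                + float(weights @ access)
                + float(rng.normal(0.0, sig_e))
            )
            expression[tg] = max(value, 0.0)
        for tf in truth.tf_ids:
            expression[tf] = max(
                truth.tf_expression[tf] * float(rng.lognormal(0.0, 0.1)), 0.0
            )
        res_r = [
            RegulatoryElement(re_.interval, float(a), re_.sequence)
            for re_, a in zip(truth.res, access)
        ]
        samples.append(PairedSample(f"rep{r + 1}", res_r, expression))
    return networks, samples


# ---------------------------------------------------------------------------
# SNP panels
# ---------------------------------------------------------------------------


def simulate_snp_panel(
    truth: GroundTruth,
    n_causal: int,
    n_background: int,
    n_traits: int = 3,
    seed: int = 0,
) -> list[SnpRecord]:
    """Causal SNPs inside truth CRMs with min-trait p ~ 10^-U(5, 9);
    background SNPs uniform over the genome with U(0, 1] p-values."""
    rng = np.random.default_rng(seed)
    traits = [f"trait{t + 1}" for t in range(n_traits)]
    crm_ivs = sorted(
        {iv for t in truth.network for iv in t.crm},
        key=lambda iv: (iv.chrom, iv.start),
    )
    if n_causal > 0 and not crm_ivs:
        raise ValidationError("truth network has no CRMs to host causal SNPs")
    crm_bases = sum(len(iv) for iv in crm_ivs)
    if n_causal > crm_bases:
        raise ValidationError(
            f"{n_causal} causal SNPs exceed {crm_bases} CRM bases"
        )

    snps: list[SnpRecord] = []

    def make_snp(chrom: str, pos: int, pvals: dict[str, float]) -> SnpRecord:
        ref = truth.genome[chrom][pos]
        alts = [b for b in _BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        return SnpRecord(chrom, pos, f"rs{len(snps) + 1:06d}", ref, alt, pvals)

    if n_causal > 0:
        lengths = np.array([len(iv) for iv in crm_ivs], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(n_causal):
            iv = crm_ivs[int(rng.choice(len(crm_ivs), p=probs))]
            pos = int(rng.integers(iv.start, iv.end))
            lead = traits[int(rng.integers(n_traits))]
            lead_p = float(10.0 ** -rng.uniform(5.0, 9.0))
            pvals = {
                t: lead_p if t == lead else float(rng.uniform(0.01, 1.0))
                for t in traits
            }
            snps.append(make_snp(iv.chrom, pos, pvals))
    chroms = list(truth.genome_index)
    lengths = np.array([truth.genome_index[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_background):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        pos = int(rng.integers(truth.genome_index[chrom]))
        pvals = {t: float(rng.uniform(1e-12, 1.0)) for t in traits}
        snps.append(make_snp(chrom, pos, pvals))
    return snps


# ---------------------------------------------------------------------------
# On-disk emission (consumed by the CLI)
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the generated instance as plain-text files every CLI
    subcommand can consume; returns the path map."""
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "sizes": outdir / "genome.sizes",
        "res": outdir / "res.bed",
        "pwms": outdir / "motifs.jaspar",
        "panel": outdir / "panel_expression.tsv",
        "truth": outdir / "truth_network.tsv",
        "candidates": outdir / "candidates.tsv",
    }
    fio.write_fasta(truth.genome, paths["genome"])
    fio.write_chrom_sizes(truth.genome_index, paths["sizes"])
    fio.write_bed(
        [
            GenomicInterval(
                re_.interval.chrom, re_.interval.start, re_.interval.end,
                re_.interval.id, re_.accessibility,
            )
            for re_ in truth.res
        ],
        paths["res"],
    )
    fio.write_pwm_counts(truth.pwm_counts, paths["pwms"])
    fio.write_expression_matrix(truth.panel_expr, paths["panel"])
    truth.network.write_tsv(paths["truth"])
    with open(paths["candidates"], "w", encoding="utf-8") as handle:
        handle.write("tg\tchrom\tstart\tend\n")
        for tg, ks in truth.candidates.items():
            for k in ks:
                iv = truth.res[k].interval
                handle.write(f"{tg}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return paths
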