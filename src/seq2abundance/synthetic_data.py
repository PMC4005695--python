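"""Synthetic genomes, expression tables and single-cell noise profiles.

The generator emulates the statistical structure the analysis assumes, with
stored ground truth for recovery tests:

* gene sequences whose codon bias and Shine-Dalgarno motif strength covary
  with a latent expression level e_g ~ N(0, 1) — codons come from a mixture
  of a uniform-synonymous and a preferred-codon distribution with mixing
  weight logistic(1.2 e_g), and the SD hexamer is drawn from the PWM blended
  with a uniform background with weight logistic(0.6 e_g + 0.8);
* log-scale mRNA abundance correlated with e_g;
* protein abundance realized exactly as the linear model assumes:
  z(log10 protein) = sum_i beta_i xz_i + eps, where xz are the z-scored
  *realized* sequence features of the generated genes (feature extraction is
  on the tested path, not short-circuited through latent columns);
* per-gene CoV following an inverse-mean law sqrt(a/mu + c0) plus
  gene-specific planted offsets delta_g.

Default effect sizes: beta(mrna_level) = 0.55, beta(cai) = 0.25, 14 further
active predictors with |beta| in [0.06, 0.15] spread over TIR and CDS
features, residual noise sd 0.55, n = 800 genes.  Generated protein means
span roughly 1..10^4 molecules per cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_catalog import (
    FORWARD_TABLE,
    MANIFEST,
    MRNA_COLUMN,
    FeatureTable,
    default_cai_weights,
    default_sd_pwm,
    group_of_column,
    impute_hybrid_features,
    sequence_feature_frame,
)
from .noise_analysis import NoiseRecord, make_noise_records
from .sequence_io import (
    ExpressionRecord,
    GeneAnnotation,
    GeneRegions,
    extract_all_regions,
    reverse_complement,
    screen_aberrant_genes,
)

DEFAULT_N_GENES = 800
DEFAULT_NOISE_SD = 0.55

#: the 16 active predictors of the default bundle (z-scored feature space).
#: Chosen over mutually weakly correlated features — non-preferred codons,
#: amino acids from families disjoint from the codon actives, independently
#: drawn TIR/stop/length properties — so each active carries identifiable
#: marginal signal next to the dominant mRNA and CAI effects.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "mrna_level": 0.55,
    "cai": 0.25,
    "exterior_loop_dg": 0.12,
    "sd_best_score": 0.10,
    "tir_fold_dg": 0.11,
    "spacing_deviation_from_optimum": -0.10,
    "codon_TCA": 0.14,
    "codon_ACA": -0.13,
    "codon_CGG": -0.12,
    "codon_GGA": 0.12,
    "aa_E": 0.14,
    "aa_H": 0.12,
    "aa_F": 0.11,
    "aa_M": -0.13,
    "protein_length": -0.12,
    "stop_TAA": 0.11,
}

_AA_BACKGROUND = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.044, "E": 0.058, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.105, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.014, "Y": 0.028, "V": 0.070,
}

_UTR_BACKGROUND = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}


@dataclass(frozen=True)
class CovLaw:
    """CoV = sqrt(a / mu + c0) + delta_g, delta from planted offsets."""

    a: float = 1.0
    c0: float = 0.0
    planted_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.a < 0 or self.c0 < 0:
            raise ValueError("cov law parameters must be nonnegative")


@dataclass
class GroundTruth:
    true_beta: dict[str, float]
    latent_expression: dict[str, float]
    noise_sd: float
    cov_law: CovLaw
    seed: int
    signal_variance: float = math.nan  # empirical Var of X beta over genes

    @property
    def active_set(self) -> set[str]:
        return {k for k, v in self.true_beta.items() if v != 0}

    @property
    def population_r2(self) -> float:
        return self.signal_variance / (self.signal_variance + self.noise_sd**2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_beta": self.true_beta,
                    "latent_expression": self.latent_expression,
                    "noise_sd": self.noise_sd,
                    "cov_law": {
                        "a": self.cov_law.a,
                        "c0": self.cov_law.c0,
                        "planted_offsets": self.cov_law.planted_offsets,
                    },
                    "seed": self.seed,
                    "signal_variance": self.signal_variance,
                },
                indent=1,
            )
        )


@dataclass(frozen=True)
class GeneSimParams:
    mean_protein_length: int = 150          # codons, lognormal around this
    length_log_sd: float = 0.35
    min_length: int = 60                    # codons
    max_length: int = 400
    codon_bias_slope: float = 1.2           # m_g = logistic(slope * e_g)
    sd_bias_slope: float = 0.6              # PWM blend weight vs latent
    sd_bias_offset: float = 0.8
    sd_spacing: tuple[int, int] = (4, 12)   # inclusive nt between SD and start
    start_codon_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)  # ATG/GTG/TTG
    stop_codon_probs: tuple[float, float, float] = (0.60, 0.20, 0.20)   # TAA/TAG/TGA
    spacer_length: int = 30
    minus_strand_fraction: float = 0.5


@dataclass
class SimulatedGenome:
    contig_id: str
    sequence: str
    annotations: list[GeneAnnotation]
    latent: dict[str, float]


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in FORWARD_TABLE.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in fams.items()}


def _preferred_codons() -> dict[str, str]:
    w = default_cai_weights().w
    return {aa: max(cs, key=lambda c: w[c]) for aa, cs in _families().items()}


def simulate_genes(
    n: int,
    params: GeneSimParams | None = None,
    seed: int = 0,
) -> SimulatedGenome:
    """Generate ``n`` valid genes on one contig (FASTA/GFF3-compatible).

    Every gene passes :func:`~seq2abundance.sequence_io.screen_aberrant_genes`
    by construction and has a full 25-nt upstream window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or GeneSimParams()
    rng = np.random.default_rng(seed)
    fams = _families()
    preferred = _preferred_codons()
    pwm = default_sd_pwm()
    pwm_freqs = pwm.frequencies  # 4 x 6, rows A C G T
    aas = sorted(_AA_BACKGROUND)
    aa_p = np.array([_AA_BACKGROUND[a] for a in aas])
    aa_p = aa_p / aa_p.sum()
    utr_bases = sorted(_UTR_BACKGROUND)
    utr_p = np.array([_UTR_BACKGROUND[b] for b in utr_bases])
    utr_p = utr_p / utr_p.sum()

    pieces: list[str] = []
    annotations: list[GeneAnnotation] = []
    latent: dict[str, float] = {}
    pos = 0  # 0-based running position on the contig

    for g in range(n):
        gene_id = f"sg{g:04d}"
        e = float(rng.normal())
        latent[gene_id] = e

        # --- CDS ---
        L = int(
            np.clip(
                round(math.exp(rng.normal(math.log(params.mean_protein_length),
                                          params.length_log_sd))),
                params.min_length,
                params.max_length,
            )
        )
        start = ["ATG", "GTG", "TTG"][rng.choice(3, p=params.start_codon_probs)]
        stop = ["TAA", "TAG", "TGA"][rng.choice(3, p=params.stop_codon_probs)]
        m = _logistic(params.codon_bias_slope * e)
        body = []
        aa_draws = rng.choice(len(aas), size=L - 1, p=aa_p)
        for ai in aa_draws:
            aa = aas[ai]
            if rng.random() < m:
                body.append(preferred[aa])
            else:
                fam = fams[aa]
                body.append(fam[rng.integers(len(fam))])
        cds = start + "".join(body) + stop

        # --- upstream 25 nt with an SD hexamer ---
        lam = _logistic(params.sd_bias_slope * e + params.sd_bias_offset)
        s_lo, s_hi = params.sd_spacing
        spacing = int(rng.integers(s_lo, s_hi + 1))
        up = list(rng.choice(utr_bases, size=25, p=utr_p))
        sd_start = 25 - spacing - 6
        for k in range(6):
            col = lam * pwm_freqs[:, k] + (1 - lam) * 0.25
            up[sd_start + k] = "ACGT"[rng.choice(4, p=col / col.sum())]
        upstream = "".join(up)

        # --- placement ---
        spacer = "".join(rng.choice(utr_bases, size=params.spacer_length, p=utr_p))
        minus = rng.random() < params.minus_strand_fraction
        block = upstream + cds
        if minus:
            block = reverse_complement(block)
            cds_start0 = pos + len(spacer)  # revcomp(cds) leads the block
            ann = GeneAnnotation(
                gene_id=gene_id,
                start=cds_start0 + 1,
                end=cds_start0 + len(cds),
                strand="-",
                contig_id="synthetic_contig",
            )
        else:
            cds_start0 = pos + len(spacer) + len(upstream)
            ann = GeneAnnotation(
                gene_id=gene_id,
                start=cds_start0 + 1,
                end=cds_start0 + len(cds),
                strand="+",
                contig_id="synthetic_contig",
            )
        pieces.append(spacer + block)
        pos += len(spacer) + len(block)
        annotations.append(ann)

    # trailing spacer so minus-strand genes at the end have upstream room
    pieces.append("".join(rng.choice(utr_bases, size=params.spacer_length, p=utr_p)))
    return SimulatedGenome(
        contig_id="synthetic_contig",
        sequence="".join(pieces),
        annotations=annotations,
        latent=latent,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimParams:
    mrna_latent_corr: float = 0.6
    mrna_log_mean: float = 0.5
    mrna_log_sd: float = 0.6
    # protein means span ~1..10^4 molecules/cell (z(log10 PA) has sd ~1,
    # so +-3 sigma covers about 2.0 +- 2.0 decades)
    protein_log_mean: float = 2.0
    protein_log_sd: float = 0.67


def _zscore_frame(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (df - df.mean()) / sd


def simulate_expression(
    features: pd.DataFrame | FeatureTable,
    latent: Mapping[str, float],
    true_beta: Mapping[str, float] = DEFAULT_TRUE_BETA,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    params: ExpressionSimParams | None = None,
) -> tuple[list[ExpressionRecord], GroundTruth]:
    """Realize the linear model on the z-scored realized features.

    ``features`` is the (imputed) sequence-feature frame of the generated
    genes.  mRNA abundance is log-normal, correlated with the latent level;
    z(log10 protein) = X_z beta + eps with eps ~ N(0, noise_sd).
    """
    params = params or ExpressionSimParams()
    df = features.data if isinstance(features, FeatureTable) else features
    unknown = [k for k in true_beta if k != MRNA_COLUMN and k not in df.columns]
    if unknown:
        raise ValueError(f"unknown predictors in true_beta: {unknown}")
    rng = np.random.default_rng(seed)
    n = len(df)
    e = np.array([latent[g] for g in df.index])

    rho = params.mrna_latent_corr
    mrna_z = rho * e + math.sqrt(1 - rho**2) * rng.normal(size=n)
    mrna_z = (mrna_z - mrna_z.mean()) / mrna_z.std()
    mrna_level = 10 ** (params.mrna_log_mean + params.mrna_log_sd * mrna_z)

    design = _zscore_frame(df.copy())
    design[MRNA_COLUMN] = mrna_z
    signal = np.zeros(n)
    for name, b in true_beta.items():
        signal += b * design[name].to_numpy()
    eps = rng.normal(scale=noise_sd, size=n)
    y_z = signal + eps
    protein_mean = 10 ** (
        params.protein_log_mean + params.protein_log_sd * y_z
    )

    records = [
        ExpressionRecord(
            gene_id=g,
            mrna_level=float(mrna_level[i]),
            protein_mean=float(protein_mean[i]),
            protein_variance=0.0,
        )
        for i, g in enumerate(df.index)
    ]
    truth = GroundTruth(
        true_beta=dict(true_beta),
        latent_expression={g: float(v) for g, v in zip(df.index, e)},
        noise_sd=noise_sd,
        cov_law=CovLaw(),
        seed=seed,
        signal_variance=float(signal.var()),
    )
    return records, truth


def simulate_noise_profile(
    protein_means: Sequence[float] | np.ndarray,
    cov_law: CovLaw,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (variance, CoV) under the inverse-mean law plus offsets.

    ``planted_offsets`` is keyed by integer row position.  ``jitter_sd``
    adds gene-specific biological scatter around the law (N(0, jitter_sd)
    on the CoV scale, seeded); the default of 0 keeps the law exact.
    """
    mu = np.asarray(protein_means, float)
    if np.any(mu <= 0):
        raise ValueError("protein means must be positive")
    delta = np.zeros(len(mu))
    for key, d in cov_law.planted_offsets.items():
        delta[int(key)] = d
    cov = np.sqrt(cov_law.a / mu + cov_law.c0) + delta
    if jitter_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1031]))
        cov = np.maximum(cov + rng.normal(scale=jitter_sd, size=len(mu)), 0.01)
    variance = (cov * mu) ** 2
    return variance, cov


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    genome: SimulatedGenome
    regions: list[GeneRegions]
    feature_table: FeatureTable
    expression: list[ExpressionRecord]
    noise_records: list[NoiseRecord]
    truth: GroundTruth

    @property
    def response(self) -> np.ndarray:
        """log10 protein mean, aligned with the feature table rows."""
        by_id = {r.gene_id: r.protein_mean for r in self.expression}
        return np.log10([by_id[g] for g in self.feature_table.data.index])


def generate_bundle(
    n: int = DEFAULT_N_GENES,
    seed: int = 0,
    true_beta: Mapping[str, float] = DEFAULT_TRUE_BETA,
    noise_sd: float = DEFAULT_NOISE_SD,
    gene_params: GeneSimParams | None = None,
    expression_params: ExpressionSimParams | None = None,
    cov_a: float = 1.0,
    cov_c0: float = 0.0,
    planted_fraction: float = 0.10,
    planted_delta: float = 0.30,
    cov_jitter_sd: float = 0.05,
    coupled_noise: bool = True,
) -> SyntheticBundle:
    """Generate the default study bundle: genome, features, expression, noise.

    With ``coupled_noise`` the CoV offsets are planted on the genes with the
    lowest mRNA and highest translation-efficiency contributions (top decile
    of the contrast), mirroring the qualitative noise structure the analysis
    probes; otherwise a random subset is planted.  All randomness derives
    from ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2014]))
    genome = simulate_genes(n, params=gene_params, seed=seed)
    regions, skipped = extract_all_regions(
        {genome.contig_id: genome.sequence}, genome.annotations
    )
    if skipped:
        raise AssertionError(f"generator produced unextractable genes: {skipped}")
    valid, aberrant = screen_aberrant_genes(regions)
    if aberrant:
        raise AssertionError(f"generator produced aberrant genes: {aberrant}")

    seq_df = sequence_feature_frame(valid)
    seq_df, imputed = impute_hybrid_features(seq_df)
    records, truth = simulate_expression(
        seq_df,
        genome.latent,
        true_beta=true_beta,
        noise_sd=noise_sd,
        seed=seed,
        params=expression_params,
    )
    df = seq_df.copy()
    df[MRNA_COLUMN] = [math.log10(r.mrna_level) for r in records]
    table = FeatureTable(data=df, manifest=MANIFEST, imputed=imputed)

    # plant CoV offsets
    n_plant = int(round(planted_fraction * len(df)))
    design = _zscore_frame(seq_df)
    if coupled_noise:
        te = np.zeros(len(df))
        for name, b in truth.true_beta.items():
            if name != MRNA_COLUMN and group_of_column(name) in ("TIR", "CDS"):
                te += b * design[name].to_numpy()
        te = (te - te.mean()) / te.std()
        mrna_z = np.asarray(df[MRNA_COLUMN])
        mrna_z = (mrna_z - mrna_z.mean()) / mrna_z.std()
        # balanced contrast: noisy genes are low-transcription AND
        # high-translation-efficiency in equal measure
        score = te - mrna_z
        planted_idx = np.argsort(score)[::-1][:n_plant]
    else:
        planted_idx = rng.choice(len(df), size=n_plant, replace=False)
    offsets = {int(i): planted_delta for i in planted_idx}
    cov_law = CovLaw(a=cov_a, c0=cov_c0, planted_offsets=offsets)
    truth.cov_law = cov_law

    means = np.array([r.protein_mean for r in records])
    variances, covs = simulate_noise_profile(
        means, cov_law, seed=seed, jitter_sd=cov_jitter_sd
    )
    records = [
        ExpressionRecord(r.gene_id, r.mrna_level, r.protein_mean, float(v))
        for r, v in zip(records, variances)
    ]
    noise = make_noise_records(
        [r.gene_id for r in records], means, variances=variances
    )
    return SyntheticBundle(
        genome=genome,
        regions=valid,
        feature_table=table,
        expression=records,
        noise_records=noise,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + GFF3 + expression TSV + ground-truth JSON + feature TSV."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .sequence_io import write_expression_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "genome.gff3",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "ground_truth.json",
        "features": outdir / "features.tsv",
    }
    rec = SeqRecord(
        Seq(bundle.genome.sequence),
        id=bundle.genome.contig_id,
        description="synthetic genome",
    )
    SeqIO.write([rec], paths["fasta"], "fasta")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {bundle.genome.contig_id} 1 "
            f"{len(bundle.genome.sequence)}\n"
        )
        for a in bundle.genome.annotations:
            fh.write(
                f"{a.contig_id}\tseq2abundance\tCDS\t{a.start}\t{a.end}\t.\t"
                f"{a.strand}\t0\tID={a.gene_id};locus_tag={a.gene_id}\n"
            )
    write_expression_tsv(bundle.expression, paths["expression"])
    bundle.truth.to_json(paths["truth"])
    bundle.feature_table.to_tsv(paths["features"])
    return paths
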