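"""The 107-feature sequence catalog and design-table assembly.

Per gene, 16 features are computed on the 55-nt translation initiation
region (TIR) and 91 on the coding sequence (CDS): Shine-Dalgarno motif
scores and spacing, 16S:SD hybridization energetics (including the exterior
loop free energy), TIR folding/accessibility, start-codon identity, the 61
sense-codon and 20 amino-acid relative frequencies, CAI, tAI, nucleotide
content, protein length and stop-codon identity.  Together with the log10
mRNA level this yields a 108-predictor design table.

The manifest is fixed and versioned here; the authoritative published
feature list is not available, so this is a documented reconstruction
constrained to exactly 107 features, enforced by test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .rna_energy import (
    EnergyModel,
    cofold_duplex,
    exterior_loop_energy,
    fold_mfe,
    structure_statistics,
)
from .sequence_io import TIR_UPSTREAM, GeneRegions, ExpressionRecord

logger = logging.getLogger(__name__)

FORWARD_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(FORWARD_TABLE))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(FORWARD_TABLE.values())))
STOP_CODONS = ("TAA", "TAG", "TGA")
SINGLE_CODON_FAMILIES = frozenset({"ATG", "TGG"})  # Met, Trp

#: 3' tail (13 nt) of the small-subunit 16S rRNA, 5'->3'; the anti-SD probe.
DEFAULT_ANTI_SD = "GAUCACCUCCUUA"

#: rank-window around the start codon used for accessibility, TIR coordinates
#: -4..+16 (0-based half-open indices into the 55-nt TIR).
DEFAULT_ACCESSIBILITY_WINDOW = (TIR_UPSTREAM - 4, TIR_UPSTREAM + 16)

DEFAULT_OPTIMAL_SPACING = 7
DEFAULT_SD_SCORE_THRESHOLD = 0.0

TIR_FEATURES: tuple[str, ...] = (
    "sd_best_score",
    "sd_best_position",
    "sd_start_spacing",
    "spacing_deviation_from_optimum",
    "hybrid_total_dg",
    "duplex_dg",
    "exterior_loop_dg",
    "duplex_length",
    "tir_fold_dg",
    "tir_accessibility",
    "tir_unpaired_count",
    "start_ATG",
    "start_GTG",
    "start_TTG",
    "sd_motif_count_above_threshold",
    "external_init_score_passthrough",
)

CDS_FEATURES: tuple[str, ...] = tuple(
    [f"codon_{c}" for c in SENSE_CODONS]
    + [f"aa_{a}" for a in AMINO_ACIDS]
    + [
        "cai",
        "tai",
        "at_content",
        "a_content",
        "gc_content",
        "gc3_content",
        "protein_length",
        "stop_TAA",
        "stop_TAG",
        "stop_TGA",
    ]
)

MANIFEST: tuple[str, ...] = TIR_FEATURES + CDS_FEATURES
assert len(MANIFEST) == 107

MRNA_COLUMN = "mrna_level"

#: hybridization features that may be not-available (sentinel) and are imputed
HYBRID_ENERGY_FEATURES = ("hybrid_total_dg", "duplex_dg", "exterior_loop_dg")


def group_of_column(name: str) -> str:
    if name == MRNA_COLUMN:
        return "mRNA"
    if name in TIR_FEATURES:
        return "TIR"
    if name in CDS_FEATURES:
        return "CDS"
    raise KeyError(name)


# ---------------------------------------------------------------------------
# Position weight matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """4 x L position frequency matrix over A, C, G, T with a background."""

    frequencies: np.ndarray  # rows A, C, G, T; columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape[0] != 4 or f.shape[1] < 1:
            raise ValueError("PWM must be 4 x L with L >= 1")
        if not np.allclose(f.sum(axis=0), 1.0):
            raise ValueError("PWM frequency columns must sum to 1")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "background", np.asarray(self.background, float))

    @property
    def length(self) -> int:
        return self.frequencies.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, background=None, pseudocount: float = 0.0):
        counts = np.asarray(counts, dtype=float)
        freqs = counts / counts.sum(axis=0, keepdims=True)
        kwargs = {}
        if background is not None:
            kwargs["background"] = background
        return cls(frequencies=freqs, pseudocount=pseudocount, **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, background=None, pseudocount: float = 0.0):
        """Tab table: 4 rows labelled A,C,G,T x L columns, counts or frequencies."""
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        counts = df.loc[list("ACGT")].to_numpy(dtype=float)
        return cls.from_counts(counts, background=background, pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        """log2((f + pseudocount) / background), per position."""
        return np.log2(
            (self.frequencies + self.pseudocount) / self.background[:, None]
        )

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length must equal PWM length")
        lo = self.log_odds()
        idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
        return float(sum(lo[idx[b], k] for k, b in enumerate(window.upper())))


@lru_cache(maxsize=1)
def default_sd_pwm() -> PWM:
    with resources.as_file(
        resources.files("seq2abundance.data").joinpath("sd_pwm.tsv")
    ) as p:
        return PWM.from_tsv(p, pseudocount=0.01)


def score_sd_motif(
    tir_seq: str,
    pwm: PWM,
    scan_window: tuple[int, int] | None = None,
) -> tuple[float, int, int]:
    """Scan the upstream part of the TIR for the best PWM hit.

    ``scan_window`` is a 0-based half-open interval into the TIR and must lie
    in its upstream part (positions -25..-1, i.e. indices 0..25).  Returns
    ``(best_score, best_offset, spacing)`` where ``best_offset`` is the TIR
    index of the motif start and ``spacing`` is the number of nucleotides
    between the motif's last base and the first base of the start codon.
    """
    if scan_window is None:
        scan_window = (0, TIR_UPSTREAM)
    w0, w1 = scan_window
    L = pwm.length
    if w1 - w0 < L:
        raise ValueError(f"scan window {scan_window} shorter than motif length {L}")
    seq = tir_seq.upper().replace("U", "T")
    best_score, best_offset = -math.inf, w0
    for u0 in range(w0, w1 - L + 1):
        sc = pwm.score(seq[u0 : u0 + L])
        if sc > best_score:
            best_score, best_offset = sc, u0
    spacing = TIR_UPSTREAM - best_offset - L
    return best_score, best_offset, spacing


def count_sd_motifs(
    tir_seq: str,
    pwm: PWM,
    threshold: float = DEFAULT_SD_SCORE_THRESHOLD,
    scan_window: tuple[int, int] | None = None,
) -> int:
    """Number of scan offsets scoring at or above ``threshold``."""
    if scan_window is None:
        scan_window = (0, TIR_UPSTREAM)
    w0, w1 = scan_window
    L = pwm.length
    seq = tir_seq.upper().replace("U", "T")
    return sum(
        1
        for u0 in range(w0, w1 - L + 1)
        if pwm.score(seq[u0 : u0 + L]) >= threshold
    )


# ---------------------------------------------------------------------------
# Codon adaptation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonWeightTable:
    w: dict[str, float]
    source: str  # "cai" | "tai"


def _synonymous_families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in FORWARD_TABLE.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def relative_adaptiveness(
    reference_codon_counts: Mapping[str, int], floor: float = 0.01
) -> CodonWeightTable:
    """CAI weights: within each synonymous family w = count / max family count."""
    if not reference_codon_counts:
        raise ValueError("empty reference codon counts")
    w: dict[str, float] = {}
    for aa, family in _synonymous_families().items():
        mx = max(reference_codon_counts.get(c, 0) for c in family)
        if mx == 0:
            for c in family:
                w[c] = 1.0
            continue
        for c in family:
            cnt = reference_codon_counts.get(c, 0)
            w[c] = cnt / mx if cnt > 0 else floor
    return CodonWeightTable(w=w, source="cai")


@lru_cache(maxsize=1)
def default_cai_weights() -> CodonWeightTable:
    with resources.as_file(
        resources.files("seq2abundance.data").joinpath("cai_reference_counts.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return relative_adaptiveness(dict(zip(df["codon"], df["count"])))


def _codons(cds_seq: str) -> list[str]:
    seq = cds_seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def cai(cds_seq: str, weights: CodonWeightTable) -> float:
    """Geometric mean of CAI weights over the CDS, excluding the stop codon
    and the single-codon families (ATG, TGG)."""
    codons = _codons(cds_seq)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    used = [c for c in codons if c in FORWARD_TABLE and c not in SINGLE_CODON_FAMILIES]
    if not used:
        raise ValueError("CDS contains only excluded codons")
    logs = [math.log(weights.w[c]) for c in used]
    return math.exp(sum(logs) / len(logs))


# -- tAI ---------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: wobble selective-constraint penalties s for the non-Watson-Crick readings,
#: dos Reis-style: codon third base -> (WC anticodon wobble base, alt wobble
#: base, alt penalty)
_WOBBLE_RULES = {
    "T": ("A", "G", 0.41),
    "C": ("G", "A", 0.28),
    "A": ("T", "A", 0.9999),
    "G": ("C", "T", 0.68),
}


def build_tai_weights(
    trna_copies: Mapping[str, int],
) -> CodonWeightTable:
    """tAI weights from tRNA gene copy numbers with wobble penalties.

    For each sense codon W = (1-s_wc)*tGCN(wc anticodon) +
    (1-s_alt)*tGCN(alt anticodon); weights are normalized to max 1 and
    zero-availability codons receive the geometric mean of nonzero weights.
    """
    raw: dict[str, float] = {}
    for codon in SENSE_CODONS:
        wc_wobble, alt_wobble, s_alt = _WOBBLE_RULES[codon[2]]
        tail = _COMP[codon[1]] + _COMP[codon[0]]
        wc_anticodon = wc_wobble + tail
        alt_anticodon = alt_wobble + tail
        W = trna_copies.get(wc_anticodon, 0) * 1.0
        W += (1.0 - s_alt) * trna_copies.get(alt_anticodon, 0)
        raw[codon] = W
    mx = max(raw.values())
    if mx == 0:
        raise ValueError("no tRNA copies cover any codon")
    w = {c: v / mx for c, v in raw.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return CodonWeightTable(
        w={c: (v if v > 0 else gm) for c, v in w.items()}, source="tai"
    )


@lru_cache(maxsize=1)
def default_tai_weights() -> CodonWeightTable:
    with resources.as_file(
        resources.files("seq2abundance.data").joinpath("trna_gene_copy_numbers.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return build_tai_weights(dict(zip(df["anticodon"], df["copies"])))


def tai(cds_seq: str, tai_weights: CodonWeightTable) -> float:
    """Geometric mean of tAI weights over all sense codons of the CDS."""
    codons = _codons(cds_seq)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    used = [c for c in codons if c in FORWARD_TABLE]
    if not used:
        raise ValueError("CDS contains no sense codons")
    logs = [math.log(tai_weights.w[c]) for c in used]
    return math.exp(sum(logs) / len(logs))


# ---------------------------------------------------------------------------
# Composition features
# ---------------------------------------------------------------------------

def composition_features(regions: GeneRegions) -> dict[str, float]:
    """Codon/amino-acid usage, nucleotide content, length and stop identity."""
    cds = regions.cds_seq.upper().replace("U", "T")
    codons = _codons(cds)
    stop = codons[-1] if codons[-1] in STOP_CODONS else None
    body = codons[:-1] if stop else codons
    sense = [c for c in body if c in FORWARD_TABLE]
    n = len(sense)
    out: dict[str, float] = {}
    for c in SENSE_CODONS:
        out[f"codon_{c}"] = 0.0
    for a in AMINO_ACIDS:
        out[f"aa_{a}"] = 0.0
    for c in sense:
        out[f"codon_{c}"] += 1.0 / n
        out[f"aa_{FORWARD_TABLE[c]}"] += 1.0 / n
    out["at_content"] = sum(1 for b in cds if b in "AT") / len(cds)
    out["a_content"] = sum(1 for b in cds if b == "A") / len(cds)
    out["gc_content"] = sum(1 for b in cds if b in "GC") / len(cds)
    thirds = [c[2] for c in body]
    out["gc3_content"] = sum(1 for b in thirds if b in "GC") / len(thirds)
    out["protein_length"] = float(len(body))
    for s in STOP_CODONS:
        out[f"stop_{s}"] = 1.0 if stop == s else 0.0
    return out


# ---------------------------------------------------------------------------
# TIR features
# ---------------------------------------------------------------------------

def tir_features(
    regions: GeneRegions,
    pwm: PWM,
    energy_model: EnergyModel,
    anti_sd: str = DEFAULT_ANTI_SD,
    accessibility_window: tuple[int, int] = DEFAULT_ACCESSIBILITY_WINDOW,
    optimal_spacing: int = DEFAULT_OPTIMAL_SPACING,
    sd_score_threshold: float = DEFAULT_SD_SCORE_THRESHOLD,
    external_init_score: float = 0.0,
) -> dict[str, float]:
    """The 16 TIR features; hybridization energies may be NaN (sentinel)."""
    tir = regions.tir_seq
    best_score, best_offset, spacing = score_sd_motif(tir, pwm)
    out: dict[str, float] = {
        "sd_best_score": best_score,
        "sd_best_position": float(best_offset - TIR_UPSTREAM),
        "sd_start_spacing": float(spacing),
        "spacing_deviation_from_optimum": float(abs(spacing - optimal_spacing)),
        "sd_motif_count_above_threshold": float(
            count_sd_motifs(tir, pwm, threshold=sd_score_threshold)
        ),
        "external_init_score_passthrough": external_init_score,
    }
    hybrid = cofold_duplex(tir, anti_sd, energy_model)
    out["hybrid_total_dg"] = hybrid.dg_total
    out["duplex_dg"] = hybrid.dg_duplex
    out["exterior_loop_dg"] = (
        exterior_loop_energy(hybrid, energy_model)
        if not hybrid.is_sentinel
        else math.nan
    )
    out["duplex_length"] = float(hybrid.duplex_length)
    structure = fold_mfe(tir, energy_model)
    unpaired, accessibility, dg = structure_statistics(structure, accessibility_window)
    out["tir_fold_dg"] = dg
    out["tir_accessibility"] = accessibility
    out["tir_unpaired_count"] = float(unpaired)
    start = regions.start_codon
    for codon in ("ATG", "GTG", "TTG"):
        out[f"start_{codon}"] = 1.0 if start == codon else 0.0
    return out


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Genes x (107 sequence features + mrna_level) design table."""

    data: pd.DataFrame  # index gene_id, columns MANIFEST + mrna_level
    manifest: tuple[str, ...] = MANIFEST
    imputed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group_of(self) -> dict[str, str]:
        return {c: group_of_column(c) for c in self.data.columns}

    def predictors(self) -> pd.DataFrame:
        return self.data

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="gene_id")
        sidecar = {
            "manifest": list(self.manifest),
            "group_of": self.group_of,
            "imputed": self.imputed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col="gene_id")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        imputed = {}
        manifest = MANIFEST
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            imputed = sidecar.get("imputed", {})
            manifest = tuple(sidecar.get("manifest", MANIFEST))
        return cls(data=data, manifest=manifest, imputed=imputed)


def sequence_feature_frame(
    genes: Sequence[GeneRegions],
    pwm: PWM | None = None,
    cai_weights: CodonWeightTable | None = None,
    tai_weights: CodonWeightTable | None = None,
    energy_model: EnergyModel | None = None,
    manifest: Sequence[str] = MANIFEST,
    anti_sd: str = DEFAULT_ANTI_SD,
    external_init_scores: Mapping[str, float] | None = None,
    **tir_kwargs,
) -> pd.DataFrame:
    """Genes x 107 sequence-feature frame; sentinel hybridization energies
    are left as NaN (see :func:`impute_hybrid_features`)."""
    pwm = pwm or default_sd_pwm()
    cai_weights = cai_weights or default_cai_weights()
    tai_weights = tai_weights or default_tai_weights()
    energy_model = energy_model or EnergyModel.default()
    external_init_scores = external_init_scores or {}

    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_ids in input")
    rows = []
    for gene in genes:
        row = tir_features(
            gene,
            pwm,
            energy_model,
            anti_sd=anti_sd,
            external_init_score=float(external_init_scores.get(gene.gene_id, 0.0)),
            **tir_kwargs,
        )
        row.update(composition_features(gene))
        row["cai"] = cai(gene.cds_seq, cai_weights)
        row["tai"] = tai(gene.cds_seq, tai_weights)
        rows.append(row)
    return pd.DataFrame(rows, index=ids)[list(manifest)]


def impute_hybrid_features(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Replace NaN hybridization energies with the column median (in place
    on a copy); returns the imputation log column -> gene ids."""
    df = df.copy()
    imputed: dict[str, list[str]] = {}
    for col in HYBRID_ENERGY_FEATURES:
        if col not in df.columns:
            continue
        mask = df[col].isna()
        if mask.any():
            med = df.loc[~mask, col].median()
            if np.isnan(med):
                med = 0.0
            df.loc[mask, col] = med
            imputed[col] = [str(i) for i in df.index[mask]]
    return df, imputed


def assemble_feature_table(
    genes: Sequence[GeneRegions],
    expression: Sequence[ExpressionRecord],
    manifest: Sequence[str] = MANIFEST,
    **feature_kwargs,
) -> FeatureTable:
    """Compute all features and assemble the 108-predictor design table.

    ``mrna_level`` enters as log10 mRNA abundance.  Not-available
    hybridization energies (no favorable 16S:SD duplex) are imputed with the
    column median over non-sentinel genes.  Genes without an expression
    record are skipped with a warning.
    """
    expr_by_id = {r.gene_id: r for r in expression}
    if len(expr_by_id) != len(expression):
        raise ValueError("duplicate gene_ids in expression records")
    kept = []
    for gene in genes:
        if gene.gene_id not in expr_by_id:
            logger.warning("no expression for %s; gene skipped", gene.gene_id)
            continue
        kept.append(gene)
    df = sequence_feature_frame(kept, manifest=manifest, **feature_kwargs)
    df, imputed = impute_hybrid_features(df)
    df[MRNA_COLUMN] = [math.log10(expr_by_id[g].mrna_level) for g in df.index]
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise ValueError(f"non-imputable NaN in columns {bad}")
    return FeatureTable(data=df, manifest=tuple(manifest), imputed=imputed)
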