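"""End-to-end orchestration: configuration, staging, reporting.

A run is described by a single declarative config (YAML or dict) holding
either real input paths (genome + annotation + expression table) or a
``simulate`` block, plus seeds and analysis settings.  ``run_pipeline``
executes sequence extraction -> feature assembly -> PLS fitting and backward
selection -> contribution decomposition -> noise analysis, writing every
intermediate as TSV/JSON so any stage can be rerun from files.  Rerunning
with the same config reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contribution_analysis import (
    abundance_groups,
    contribution_histogram2d,
    efficiency_estimates,
    group_contribution,
    variance_shares,
)
from .feature_catalog import (
    MRNA_COLUMN,
    assemble_feature_table,
    group_of_column,
)
from .model_selection import SelectionConfig, backward_eliminate
from .noise_analysis import (
    make_noise_records,
    mann_whitney,
    noise_differential,
    noise_table,
    quartile_noise_groups,
)
from .pls_regression import DEFAULT_CV_SEED, standardize
from .sequence_io import (
    extract_all_regions,
    flag_expression_outliers,
    load_annotated_genome,
    read_expression_tsv,
    screen_aberrant_genes,
    write_filter_report,
    write_regions_tsv,
)
from .synthetic_data import generate_bundle, write_bundle

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run description; exactly one of real inputs / simulate."""

    output_dir: str = "run_output"
    seed: int = DEFAULT_CV_SEED
    k_folds: int = 10
    tol: float = 0.002
    window: int = 51
    topology: str = "linear"
    protected: list[str] = field(default_factory=list)
    # real-input mode
    genome: str | None = None
    genome_format: str = "genbank"
    annotation: str | None = None
    expression: str | None = None
    outlier_sd: float = 3.0
    # simulate mode
    simulate: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        real = self.genome is not None or self.expression is not None
        if real and self.simulate is not None:
            raise ConfigError("config must use real inputs OR a simulate block")
        if not real and self.simulate is None:
            raise ConfigError("config needs input paths or a simulate block")
        if real:
            for name in ("genome", "expression"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"real-input mode requires {name!r}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
            if self.genome_format == "fasta+gff3":
                if self.annotation is None or not Path(self.annotation).exists():
                    raise ConfigError(
                        f"annotation path missing or absent: {self.annotation}"
                    )
        if self.window % 2 == 0:
            raise ConfigError("noise window must be odd")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        bundle = generate_bundle(**sim)
        write_bundle(bundle, out / "simulated")
        table = bundle.feature_table
        expression = bundle.expression
        noise_records = bundle.noise_records
        regions = bundle.regions
    else:
        contigs, annotations = load_annotated_genome(
            config.genome,
            format=config.genome_format,
            annotation_path=config.annotation,
        )
        regions, skipped = extract_all_regions(
            contigs, annotations, topology=config.topology
        )
        warnings += [f"extraction skipped {g}: {r}" for g, r in skipped]
        regions, aberrant = screen_aberrant_genes(regions)
        warnings += [f"aberrant {r.gene_id}: {why}" for r, why in aberrant]
        write_filter_report(
            skipped + [(r.gene_id, why) for r, why in aberrant],
            out / "filter_report.tsv",
        )
        expression = read_expression_tsv(config.expression)
        expression, removed = flag_expression_outliers(
            expression, sd_threshold=config.outlier_sd
        )
        warnings += [f"expression outlier removed: {r.gene_id}" for r in removed]
        table = assemble_feature_table(regions, expression)
        noise_records = make_noise_records(
            [r.gene_id for r in expression],
            [r.protein_mean for r in expression],
            variances=[r.protein_variance for r in expression],
        )
    write_regions_tsv(regions, out / "regions.tsv")
    table.to_tsv(out / "features.tsv")
    warnings += [
        f"imputed {col} for {len(genes)} gene(s)" for col, genes in table.imputed.items()
    ]

    # --- stage: model fit + selection --------------------------------------
    expr_by_id = {r.gene_id: r for r in expression}
    y = np.array(
        [math.log10(expr_by_id[g].protein_mean) for g in table.data.index]
    )
    sel = backward_eliminate(
        table,
        y,
        SelectionConfig(
            k=config.k_folds,
            seed=config.seed,
            tol=config.tol,
            protected=frozenset(config.protected),
        ),
    )
    sel.write_trajectory(out / "selection_trajectory.tsv")
    sel.final_model.to_json(
        out / "model.json",
        extra={
            "cv_r2": sel.final_cv_r2,
            "seed": config.seed,
            "surviving": sel.surviving,
        },
    )

    # --- stage: contributions ----------------------------------------------
    X = table.data[sel.surviving]
    Xz, yz, (xp, yp) = standardize(X, y)
    Xz = pd.DataFrame(Xz, index=X.index, columns=X.columns)
    group_of = {c: group_of_column(c) for c in X.columns}
    model = sel.final_model
    contribs = group_contribution(model, Xz, group_of)
    contribs.to_csv(out / "contributions.tsv", sep="\t", index_label="gene_id")
    contribution_histogram2d(contribs).to_csv(
        out / "contribution_histogram2d.tsv", sep="\t"
    )
    shares = variance_shares(model, Xz, yz, group_of)
    means = np.array([expr_by_id[g].protein_mean for g in X.index])
    abund = abundance_groups(means)
    transcription, translation, r_tt = efficiency_estimates(contribs)

    # --- stage: noise -------------------------------------------------------
    keep = set(table.data.index)
    noise_records = [r for r in noise_records if r.gene_id in keep]
    noise_records = noise_differential(noise_records, window=config.window)
    nd_by_id = {r.gene_id: r for r in noise_records}
    noise_records = [nd_by_id[g] for g in X.index]
    ntab = noise_table(noise_records)
    nd_groups = quartile_noise_groups(noise_records)
    ntab["nd_group"] = nd_groups
    ntab["abundance_group"] = abund
    ntab.to_csv(out / "noise.tsv", sep="\t")

    hi, lo = nd_groups == "high_nd", nd_groups == "low_nd"
    mrna = table.data.loc[X.index, MRNA_COLUMN].to_numpy()
    _, p_mrna = mann_whitney(mrna[hi], mrna[lo])
    _, p_te = mann_whitney(translation[hi], translation[lo])

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": int(len(X)),
        "n_predictors_initial": int(table.data.shape[1]),
        "n_predictors_final": len(sel.surviving),
        "surviving": sel.surviving,
        "cv_r2": sel.final_cv_r2,
        "variance_shares": shares.share,
        "model_r2": shares.model_r2,
        "transcription_translation_r": r_tt,
        "mann_whitney_p_mrna": p_mrna,
        "mann_whitney_p_translation": p_te,
        "warnings": warnings,
    }
    (out / "run_manifest.json").write_text(json.dumps(summary, indent=1))
    return summary
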