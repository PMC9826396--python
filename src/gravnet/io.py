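"""File formats, configuration and the pipeline driver.

Reads biallelic SNP genotypes from VCF (via cyvcf2) or a delimited dosage
matrix, round-trips YAML pipeline configuration, and runs the full
simulate -> terrain -> network -> popgen -> gravity chain into a run
directory with a manifest and a frozen copy of the resolved configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .popgen import GenotypeMatrix

__all__ = [
    "read_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "PipelineConfig",
    "load_config",
    "save_config",
    "run_pipeline",
]


def read_vcf(path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Biallelic SNP records -> dosage matrix.

    Multi-allelic records are skipped (count reported via warning); any
    genotype that is not a full diploid call (./., half-calls) is missing.
    ``populations`` maps sample id -> population label; samples without a
    mapping get label "pop0".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has zero samples")
    rows = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            skipped += 1
            continue
        gt = variant.gt_types.astype(np.int64)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = -1
        rows.append(gt)
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic/non-SNP records")
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    dosages = np.stack(rows, axis=1)
    populations = populations or {}
    labels = [populations.get(s, "pop0") for s in samples]
    return GenotypeMatrix(dosages, samples, labels)


def write_dosage_matrix(path, g: GenotypeMatrix) -> None:
    """Delimited matrix: one row per individual (id, population, dosages; -1 missing)."""
    df = g.to_dataframe()
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GenotypeMatrix.from_dataframe(df)


@dataclass
class PipelineConfig:
    """Resolved settings for a full run; defaults mirror the study's choices."""

    seed: int = 0
    outdir: str = "gravnet_run"
    prune_km: float = 10.0          # alternative: 50
    buffer_m: float | None = None   # None = native 30 m cells; {30, 90, 250, 500}
    edge_stat: str = "median"
    n_perm: int = 9999
    correlation_threshold: float = 0.70
    ci_rule: str = "normal"
    df_rule: str = "two_stratum"
    # synthetic-data knobs (used when no external rasters/nodes are given)
    simulation: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(Path(path).read_text())


def save_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(config.to_yaml())


def _versions() -> dict[str, str]:
    import cyvcf2
    import scipy
    import tifffile

    import gravnet

    return {
        "gravnet": getattr(gravnet, "__version__", "0.1.0"),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "tifffile": tifffile.__version__,
        "cyvcf2": cyvcf2.__version__,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages on a synthetic dataset and write a run directory.

    Stages: simulate (landscape + individuals + genotypes + flows), terrain
    surfaces, network design table, population-genetic statistics, gravity
    model competition and effect sizes.  Deterministic for a fixed config;
    every output CSV carries units in its header block.
    """
    from . import model as gmodel
    from .popgen import amova, euclidean_genetic_distance, gene_flow, pairwise_fst
    from .raster import write_geotiff
    from .simulate import SimulationConfig, simulate_dataset

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("prune_km", config.prune_km)
    if "grid_shape" in sim_kwargs:
        sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
    sim = SimulationConfig(**sim_kwargs)

    save_config(outdir / "config.yaml", config)
    manifest["config"] = "config.yaml"
    (outdir / "versions.json").write_text(json.dumps(_versions(), indent=2))
    manifest["versions"] = "versions.json"

    # --- simulate + terrain -------------------------------------------------
    data = simulate_dataset(sim)
    rasdir = outdir / "rasters"
    rasdir.mkdir(exist_ok=True)
    for code, grid in {**data.rasters, **data.derived}.items():
        write_geotiff(rasdir / f"{code}.tif", grid)
    manifest["rasters"] = "rasters/*.tif"
    data.nodes.to_csv(outdir / "nodes.csv", index=False)
    manifest["nodes"] = "nodes.csv  # columns: id, site, x/y in projected meters"

    # --- network design table ----------------------------------------------
    data.edge_table.to_csv(outdir / "edges.csv", index=False)
    manifest["edges"] = "edges.csv  # length in meters; at_*/btw_* on raw scale; flow unitless"

    # --- population genetics -------------------------------------------------
    g = data.genotypes
    write_dosage_matrix(outdir / "genotypes.tsv", g)
    manifest["genotypes"] = "genotypes.tsv  # diploid dosages 0/1/2, -1 missing"
    dist = euclidean_genetic_distance(g)
    flow = gene_flow(dist)
    pd.DataFrame(flow.values, index=flow.ids, columns=flow.ids).to_csv(outdir / "gene_flow.csv")
    pops = g.populations
    fst = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            fst.loc[b, a] = pairwise_fst(g, (a, b))
    fst.to_csv(outdir / "fst_matrix.csv")
    manifest["fst"] = "fst_matrix.csv  # pairwise AMOVA-based theta, lower triangle"
    am = amova(g, n_perm=min(config.n_perm, 199), seed=config.seed)
    am.to_dataframe().to_csv(outdir / "amova.csv", index=False)
    manifest["amova"] = "amova.csv"

    # --- gravity models ------------------------------------------------------
    comp = gmodel.hierarchical_competition(data.edge_table, df_rule=config.df_rule)
    comp.round_at.to_csv(outdir / "round1_at.csv", index=False)
    comp.round_btw.to_csv(outdir / "round1_btw.csv", index=False)
    comp.round_combined.to_csv(outdir / "round2_combined.csv", index=False)
    frame = gmodel.prepare_design(data.edge_table, comp.selected)
    reml = gmodel.fit_gravity(frame, "REML", config.df_rule)
    reml.params.to_csv(outdir / "final_model_reml.csv")
    es = gmodel.effect_sizes(reml, ci_rule=config.ci_rule)
    es.table.to_csv(outdir / "effect_sizes.csv")
    gmodel.interpretation_report(es).to_csv(outdir / "interpretation.csv")
    manifest["gravity"] = "round1_at.csv round1_btw.csv round2_combined.csv final_model_reml.csv effect_sizes.csv"

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
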