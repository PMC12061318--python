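"""File formats, run configuration and the end-to-end pipeline.

Genotypes are read from VCF (via cyvcf2), HapMap text or plain 0/1/2
dosage CSV; weather and phenotypes from long-format CSV; configuration
from YAML.  ``run_pipeline`` chains envirotyping → plasticity → feature
extraction → prediction, stamping every artifact with the config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envirotyping, envparams, genofeatures, plasticity, predictor
from .errors import AutoGSError, ConfigError
from .genofeatures import GenotypeMatrix
from .plasticity import TraitTable

logger = logging.getLogger(__name__)

HAPMAP_META_COLS = 11  # rs#, alleles, chrom, pos, strand, assembly, center,
#                        protLSID, assayLSID, panelLSID, QCcode

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, HapMap or dosage CSV.

    ``fmt`` is inferred from the suffix when omitted (.vcf/.vcf.gz,
    .hmp.txt, otherwise CSV).  Dosages are 0/1/2 ALT-allele counts (NaN for
    missing); coordinates are 1-based; multiallelic sites are flagged in
    the map for removal by QC.
    """
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif name.endswith((".hmp.txt", ".hapmap", ".hmp")):
            fmt = "hapmap"
        else:
            fmt = "csv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "hapmap":
        return _read_hapmap(path)
    if fmt == "csv":
        return _read_dosage_csv(path)
    raise ConfigError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols, multi = [], [], []
    for i, var in enumerate(vcf):
        if var.ploidy != 2:
            raise ConfigError(
                f"{path} record {i + 1} ({var.CHROM}:{var.POS}): ploidy "
                f"{var.ploidy} unsupported"
            )
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        cols.append(g)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, var.CHROM, var.POS))
        multi.append(len(var.ALT) > 1)
    if not rows:
        raise ConfigError(f"{path}: no variant records")
    marker_map = pd.DataFrame(
        {"chrom": [r[1] for r in rows], "pos": [r[2] for r in rows],
         "multiallelic": multi},
        index=[r[0] for r in rows],
    )
    return GenotypeMatrix(samples, np.column_stack(cols), marker_map)


def _hapmap_call_to_dosage(call: str, alleles: str) -> float:
    ref, *alt = alleles.replace("/", "").replace(",", "")
    if call in ("NN", "N", "--", "./."):
        return np.nan
    if len(call) == 1:
        call = _IUPAC_HET.get(call, call * 2)
    return float(sum(c != ref for c in call))


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = list(df.columns[HAPMAP_META_COLS:])
    if not samples:
        raise ConfigError(f"{path}: no sample columns after HapMap metadata")
    dosages = np.empty((len(samples), len(df)))
    multi = []
    for j, row in df.iterrows():
        alleles = row.iloc[1]
        multi.append(len(alleles.replace("/", "").replace(",", "")) > 2)
        for i, s in enumerate(samples):
            dosages[i, j] = _hapmap_call_to_dosage(str(row[s]), alleles)
    marker_map = pd.DataFrame(
        {"chrom": df.iloc[:, 2].astype(str).tolist(),
         "pos": df.iloc[:, 3].astype(int).tolist(),
         "multiallelic": multi},
        index=df.iloc[:, 0].tolist(),
    )
    order = np.lexsort((marker_map["pos"], marker_map["chrom"]))
    return GenotypeMatrix(samples, dosages[:, order], marker_map.iloc[order])


def _read_dosage_csv(path) -> GenotypeMatrix:
    """CSV with columns marker_id, chrom, pos then one column per sample."""
    df = pd.read_csv(path)
    required = {"marker_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: dosage CSV needs columns {sorted(required)}")
    samples = [c for c in df.columns if c not in required]
    marker_map = pd.DataFrame(
        {"chrom": df["chrom"].astype(str).to_numpy(), "pos": df["pos"].astype(int).to_numpy()},
        index=pd.Index(df["marker_id"], name=None),
    )
    dosages = df[samples].to_numpy(float).T
    order = np.lexsort((marker_map["pos"], marker_map["chrom"]))
    return GenotypeMatrix(samples, dosages[:, order], marker_map.iloc[order])


def write_dosage_csv(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.marker_map[["chrom", "pos"]].copy()
    out.insert(0, "marker_id", genotypes.marker_map.index)
    for i, s in enumerate(genotypes.samples):
        out[s] = genotypes.dosages[i]
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(envparams.WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: weather table missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_phenotypes(path, trait: str) -> TraitTable:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"genotype_id", "env_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: phenotype table needs columns {sorted(required)}")
    return TraitTable.from_long(df, trait)


def read_tam_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"marker_id", "trait", "category"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: TAM table needs columns {sorted(required)}")
    return df


def read_stage_table(path) -> envirotyping.StageThresholdTable:
    df = pd.read_csv(path, sep=None, engine="python")
    return envirotyping.StageThresholdTable(
        tuple(df["stage"].astype(str)), tuple(df["gdd_bound"].astype(float))
    )


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    weather_path: str
    phenotype_path: str
    genotype_path: str
    trait: str
    output_dir: str
    tam_path: str | None = None
    stage_table_path: str | None = None
    genotype_format: str | None = None
    tbase: float = 50.0
    tcap: float = 86.0
    pts_formula: str = "literal"
    r_threshold: float = 0.90
    flank_mode: str = "fixed_bp"
    flank_bp: int = 37_000
    cv_scheme: str = "fivefold"
    seed: int = 0
    tuning_budget: int = 50
    base_learners: tuple = predictor.DEFAULT_BASE_LEARNERS
    ep_mode: str = "reduced"
    search_space: str = "default"
    screen_n_pcs: int = 3
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for p in (cfg.weather_path, cfg.phenotype_path, cfg.genotype_path):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        return cfg

    def hash(self) -> str:
        # output location does not affect the computation
        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        payload["base_learners"] = list(self.base_learners)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write every artifact to the output dir.

    Stages: EP derivation → stage segmentation / RD_EP reduction →
    critical-window search → reaction norms and variance decomposition →
    TAM feature extraction (from a supplied TAM table, else an association
    screen on the phenotype) → stacked-ensemble CV evaluation.  A stage
    failure aborts with the stage name; artifacts written so far are kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    results: dict = dict(stamp)
    stage = "setup"
    try:
        stage = "envparams"
        weather = read_weather(config.weather_path)
        ep_tables = envparams.build_all_ep_series(
            weather, tbase=config.tbase, tcap=config.tcap, pts_formula=config.pts_formula
        )
        envparams.ep_long_table(ep_tables).to_csv(out / "ep_daily.csv", index=False)

        stage = "envirotyping"
        stage_table = (
            read_stage_table(config.stage_table_path)
            if config.stage_table_path
            else envirotyping.maize_stage_table()
        )
        rdeps = envirotyping.rdep_profiles(ep_tables, stage_table)
        rdep_long = pd.concat(
            {e: r.matrix.stack(future_stack=True) for e, r in rdeps.items()},
            names=["env_id", "ep_name", "stage"],
        ).rename("value")
        rdep_long.to_csv(out / "rdep.csv")

        stage = "plasticity"
        trait_table = read_phenotypes(config.phenotype_path, config.trait)
        env_means = plasticity.environment_trait_means(trait_table)
        windowed = envirotyping.stack_windowed_eps(rdeps)
        windows = envirotyping.critical_window_search(
            env_means, windowed, r_threshold=config.r_threshold,
            trait=config.trait, stage_labels=stage_table.stage_labels,
        )
        pd.DataFrame(
            [
                {"trait": w.trait, "ep_name": w.ep_name, "start": w.start_label,
                 "end": w.end_label, "r": w.r}
                for w in windows
            ],
            columns=["trait", "ep_name", "start", "end", "r"],
        ).to_csv(out / "critical_windows.csv", index=False)
        if not windows:
            logger.warning(
                "no critical window at |r| ≥ %.2f; EP features still used, "
                "PP parameters skipped", config.r_threshold,
            )
        pp_list = []
        for w in windows:
            series = windowed[(w.ep_name, w.start_stage, w.end_stage)]
            pp_list.extend(plasticity.fit_reaction_norms(trait_table, w, series))
        if pp_list:
            plasticity.pp_params_frame(pp_list).to_csv(out / "pp_params.csv", index=False)
        vc = plasticity.variance_decomposition(trait_table)
        results["variance_components"] = {
            "var_g": vc.var_g, "var_e": vc.var_e, "var_gxe_residual": vc.var_gxe_residual,
            "shares": list(vc.shares), "h2": vc.h2,
        }

        stage = "genofeatures"
        genotypes = read_genotypes(config.genotype_path, config.genotype_format)
        genotypes, qc_report = genofeatures.qc_filter(genotypes)
        results["qc"] = qc_report.__dict__
        if config.tam_path:
            tams = read_tam_table(config.tam_path)
            present = tams["marker_id"].isin(genotypes.marker_map.index)
            if not present.all():
                logger.warning(
                    "%d TAM(s) not in the post-QC marker map, dropped: %s",
                    int((~present).sum()),
                    tams.loc[~present, "marker_id"].head().tolist(),
                )
                tams = tams[present]
        else:
            screen = genofeatures.association_screen(
                genotypes,
                trait_table.values.mean(axis=1),
                n_pcs=config.screen_n_pcs,
            )
            hits = screen[screen["bonferroni_sig"]].index
            tams = pd.DataFrame(
                {"marker_id": hits, "trait": config.trait, "category": "Main"}
            )
        if len(tams):
            feature_sets = genofeatures.extract_tam_flanks(
                tams, genotypes, mode=config.flank_mode, flank_bp=config.flank_bp,
                trait=config.trait,
            )
            marker_set = feature_sets["All-TAMs"]
        else:
            logger.warning("no TAMs available; falling back to all markers")
            marker_set = genotypes.marker_ids

        stage = "predictor"
        features = predictor.assemble_features(
            genotypes, marker_set, rdeps, trait_table,
            ep_mode=config.ep_mode, raw_ep_tables=ep_tables,
        )
        features.provenance.rename("provenance").to_csv(out / "feature_provenance.csv")
        cv = predictor.make_cv_scheme(features.X.index, config.cv_scheme, config.seed)
        result = predictor.evaluate(
            features, cv, base_learners=config.base_learners,
            tuning_budget=config.tuning_budget, seed=config.seed,
            search_space=config.search_space,
        )
        frame = result.to_frame()
        for k, v in stamp.items():
            frame[k] = v
        frame.to_csv(out / "fold_pcc.csv", index=False)
        results["mean_pcc"] = result.mean_pcc
        results["fold_pcc"] = result.fold_pcc
        (out / "run_metadata.json").write_text(json.dumps(results, indent=2, default=str))
        return results
    except AutoGSError:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise
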