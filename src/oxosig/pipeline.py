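"""Stage orchestration: configuration, run manifests, and the analysis stages.

Each stage reads standard-format inputs, runs the corresponding library
functions, and writes tab-delimited outputs plus a run manifest (inputs,
config hash, seed, package versions) into the output directory.  All
randomness flows from a single root seed with per-stage derived streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonal import ClonalPair, accrual_rates, genotype_contrast
from .cn_groups import assign_groups, call_cnl, cnl_vs_wt_comparisons
from .signatures import cluster_by_contributions, dominant_signature, strict_refit
from .spectra import CHANNELS_96, SUB_CLASSES, build_spectrum, relative_spectrum
from .survival import kaplan_scan
from .synthetic import (
    CloneSpec,
    CohortSpec,
    make_reference,
    pseudo_signature_matrix,
    simulate_clonal_pairs,
    simulate_cohort,
    write_clonal,
    write_cohort,
)
from .variant_io import (
    ReferenceContextSource,
    read_cbs_table,
    read_clinical_table,
    read_signature_matrix,
    read_snv_catalog,
    write_signature_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "reference": {"n_chroms": 2, "length": 500000},
    "cohort": {"n_samples": 86},
    "clones": {"replicates": 2},
    "cbs_cutoff": -0.5,
    "refit": {"max_delta": 0.004, "min_relative": 0.0},
    "cluster": {"method": "complete", "metric": "euclidean"},
    "scan": {"min_group": 8, "covariate": "ca_fraction"},
}


class ConfigError(ValueError):
    """Configuration failed schema validation; message names the bad path."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config field {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config field {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys are errors."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping at top level")
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def write_manifest(out_dir: Path, config: dict, inputs: dict, stage: str) -> Path:
    payload = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": config.get("seed"),
        "versions": {
            "oxosig": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage stream derived from the root seed (< 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Generate reference, cohort, clone pairs, and signature matrix files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    ref_cfg = config["reference"]
    fasta = make_reference(
        out_dir / "reference.fa",
        n_chroms=int(ref_cfg["n_chroms"]),
        length=int(ref_cfg["length"]),
        seed=stage_seed(seed, "reference"),
    )
    reference = ReferenceContextSource(fasta)
    matrix = pseudo_signature_matrix()
    write_signature_matrix(matrix, out_dir / "signatures.tsv")

    spec = CohortSpec(
        n_samples=int(config["cohort"]["n_samples"]), seed=stage_seed(seed, "cohort")
    )
    cohort = simulate_cohort(spec, reference, matrix)
    paths = write_cohort(cohort, out_dir / "cohort")

    clone_spec = CloneSpec(
        replicates=int(config["clones"]["replicates"]), seed=stage_seed(seed, "clones")
    )
    pairs, clone_truth = simulate_clonal_pairs(clone_spec, reference, matrix)
    write_clonal(pairs, clone_truth, out_dir / "clones")

    write_manifest(out_dir, config, {"out_dir": out_dir}, "simulate")
    return {
        "reference": fasta,
        "signatures": out_dir / "signatures.tsv",
        "cohort_dir": out_dir / "cohort",
        "clone_dir": out_dir / "clones",
        **paths,
    }


def _load_catalogs(vcf_dir: Path) -> list:
    return [
        read_snv_catalog(path, path.stem) for path in sorted(vcf_dir.glob("*.vcf"))
    ]


def run_spectra(config: dict, vcf_dir: str | Path, reference_path: str | Path, out_dir: str | Path) -> Path:
    """Per-sample 6-class and 96-channel spectra tables from VCFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = ReferenceContextSource(reference_path)
    rows96, rows6 = {}, {}
    for catalog in _load_catalogs(Path(vcf_dir)):
        spectrum = build_spectrum(catalog, reference)
        rel = relative_spectrum(spectrum)
        rows96[catalog.sample_id] = np.concatenate([spectrum.counts96, rel.freq96])
        rows6[catalog.sample_id] = np.concatenate(
            [spectrum.counts6, rel.freq6, [spectrum.n_excluded, catalog.n_indels]]
        )
    cols96 = [f"n:{c}" for c in CHANNELS_96] + [f"f:{c}" for c in CHANNELS_96]
    cols6 = (
        [f"n:{c}" for c in SUB_CLASSES]
        + [f"f:{c}" for c in SUB_CLASSES]
        + ["n_excluded", "n_indels"]
    )
    pd.DataFrame.from_dict(rows96, orient="index", columns=cols96).rename_axis(
        "sample_id"
    ).to_csv(out_dir / "spectra96.tsv", sep="\t")
    pd.DataFrame.from_dict(rows6, orient="index", columns=cols6).rename_axis(
        "sample_id"
    ).to_csv(out_dir / "spectra6.tsv", sep="\t")
    write_manifest(out_dir, config, {"vcf_dir": vcf_dir, "reference": reference_path}, "spectra")
    return out_dir / "spectra6.tsv"


def run_refit(config: dict, spectra96_path: str | Path, signatures_path: str | Path, out_dir: str | Path) -> Path:
    """Strict signature refit of each sample's 96-channel counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = read_signature_matrix(signatures_path)
    table = pd.read_csv(spectra96_path, sep="\t", index_col="sample_id")
    counts = table[[f"n:{c}" for c in CHANNELS_96]].to_numpy()
    rows = []
    for sample_id, m in zip(table.index, counts):
        refit = strict_refit(
            m,
            matrix,
            max_delta=float(config["refit"]["max_delta"]),
            min_relative=float(config["refit"]["min_relative"]),
            sample_id=str(sample_id),
        )
        dom, tie = dominant_signature(refit)
        rows.append(
            {
                "sample_id": sample_id,
                **dict(zip(matrix.names, refit.contributions)),
                **{f"rel_{n}": v for n, v in zip(matrix.names, refit.relative_contributions)},
                "retained": ",".join(refit.retained),
                "recon_cosine": refit.recon_cosine,
                "dominant": dom,
                "dominant_tie": tie,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "refit.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"spectra": spectra96_path, "signatures": signatures_path}, "refit")
    return out_dir / "refit.tsv"


def run_cluster(config: dict, refit_path: str | Path, out_dir: str | Path) -> Path:
    """Hierarchical clustering of samples on relative contributions."""
    from .signatures import RefitResult

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(refit_path, sep="\t")
    names = [c[4:] for c in table.columns if c.startswith("rel_")]
    refits = [
        RefitResult(
            sample_id=str(row["sample_id"]),
            signature_names=names,
            contributions=np.array([row[f"rel_{n}"] for n in names]),
            retained=str(row["retained"]).split(","),
            recon_cosine=float(row["recon_cosine"]),
        )
        for _, row in table.iterrows()
    ]
    clustering = cluster_by_contributions(
        refits,
        method=str(config["cluster"]["method"]),
        metric=str(config["cluster"]["metric"]),
    )
    (out_dir / "cluster.nwk").write_text(clustering.to_newick())
    clustering.similarity.rename_axis("sample_id").to_csv(
        out_dir / "cosine_similarity.tsv", sep="\t"
    )
    pd.DataFrame({"sample_id": clustering.leaf_order}).to_csv(
        out_dir / "leaf_order.tsv", sep="\t", index=False
    )
    two_cut = clustering.cut(2)
    pd.DataFrame(
        {"sample_id": list(two_cut), "cluster2": list(two_cut.values())}
    ).to_csv(out_dir / "clusters_k2.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"refit": refit_path}, "cluster")
    return out_dir / "cluster.nwk"


def run_cnl(config: dict, cbs_path: str | Path, spectra6_path: str | Path, out_dir: str | Path) -> Path:
    """Loss calls, group assignment and CNL-vs-WT Welch comparisons."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls = call_cnl(read_cbs_table(cbs_path), cutoff=float(config["cbs_cutoff"]))
    grouping_calls = [c for c in calls if c.gene in ("MUTYH", "OGG1")]
    groups = assign_groups(grouping_calls)
    spectra6 = pd.read_csv(spectra6_path, sep="\t", index_col="sample_id")
    ca = dict(spectra6["f:C>A"])
    out = pd.DataFrame(
        {
            "sample_id": list(groups),
            "group": list(groups.values()),
            "ca_fraction": [ca.get(s, np.nan) for s in groups],
        }
    )
    out.to_csv(out_dir / "cnl_groups.tsv", sep="\t", index=False)
    comparisons = cnl_vs_wt_comparisons(groups, {k: v for k, v in ca.items()})
    rows = [
        {
            "contrast": f"{c.group_labels[0]}_vs_{c.group_labels[1]}",
            "n_a": c.n[0],
            "n_b": c.n[1],
            "mean_a": c.means[0],
            "mean_b": c.means[1],
            "t": c.t,
            "df": c.df,
            "p": c.p,
        }
        for c in comparisons.values()
    ]
    pd.DataFrame(rows).to_csv(out_dir / "cnl_tests.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"cbs": cbs_path, "spectra6": spectra6_path}, "cnl")
    return out_dir / "cnl_groups.tsv"


def run_survival(config: dict, clinical_path: str | Path, spectra6_path: str | Path, out_dir: str | Path) -> Path:
    """Cutoff scan of the C>A fraction against overall survival."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_clinical_table(clinical_path)
    spectra6 = pd.read_csv(spectra6_path, sep="\t", index_col="sample_id")
    ca = dict(spectra6["f:C>A"])
    covariate = str(config["scan"]["covariate"])
    for rec in records:
        if rec.sample_id in ca:
            rec.covariates[covariate] = ca[rec.sample_id]
    records = [r for r in records if covariate in r.covariates]
    result = kaplan_scan(records, covariate=covariate, min_group=int(config["scan"]["min_group"]))
    pd.DataFrame({"cutoff": result.cutoffs, "raw_p": result.raw_p, "chi2": result.statistics}).to_csv(
        out_dir / "scan_curve.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "best_cutoff": result.best_cutoff,
                "raw_p": result.best_raw_p,
                "bonferroni_p": result.bonferroni_p,
                "n_cutoffs": result.n_cutoffs,
                "n_high": result.n_high,
                "n_low": result.n_low,
            }
        ]
    ).to_csv(out_dir / "scan_best.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"clinical": clinical_path, "spectra6": spectra6_path}, "survival")
    return out_dir / "scan_best.tsv"


def run_clonal(config: dict, clone_dir: str | Path, reference_path: str | Path, out_dir: str | Path) -> Path:
    """Per-pair accrual rates and the knockout-vs-WT genotype contrasts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clone_dir = Path(clone_dir)
    reference = ReferenceContextSource(reference_path)
    meta = pd.read_csv(clone_dir / "pairs.tsv", sep="\t")
    results = []
    for _, row in meta.iterrows():
        pair = ClonalPair(
            read_snv_catalog(clone_dir / f"{row['clone']}.vcf", str(row["clone"])),
            read_snv_catalog(clone_dir / f"{row['subclone']}.vcf", str(row["subclone"])),
            float(row["days"]),
            str(row["genotype"]),
        )
        results.append(accrual_rates(pair, reference))
    rows = [
        {
            "pair_id": r.pair_id,
            "genotype": r.genotype,
            "days": r.days,
            "n_accrued": len(r.accumulated),
            "total_rate": r.total_rate,
            **{f"rate_{c}": v for c, v in zip(SUB_CLASSES, r.class_rates)},
            **{f"frac_{c}": v for c, v in zip(SUB_CLASSES, r.class_fractions)},
            "indel_delta": r.indel_delta,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(out_dir / "clonal_rates.tsv", sep="\t", index=False)

    contrasts = []
    genotypes = {r.genotype for r in results}
    for ko in sorted(genotypes - {"WT"}):
        try:
            c = genotype_contrast(results, ko, "WT")
        except ValueError:
            continue
        contrasts.append(
            {"contrast": f"{ko}_vs_WT", "t": c.t, "df": c.df, "p": c.p, "welch": c.welch}
        )
    pd.DataFrame(contrasts).to_csv(out_dir / "clonal_tests.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"clone_dir": clone_dir, "reference": reference_path}, "clonal")
    return out_dir / "clonal_rates.tsv"


def run_report(config: dict, work_dir: str | Path, out_dir: str | Path) -> Path:
    """Aggregate per-sample C>A fraction, CNL group, dominant signature, scan."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    work_dir = Path(work_dir)
    groups = pd.read_csv(work_dir / "cnl" / "cnl_groups.tsv", sep="\t")
    refit = pd.read_csv(work_dir / "refit" / "refit.tsv", sep="\t")[
        ["sample_id", "dominant", "recon_cosine", "retained"]
    ]
    clusters = pd.read_csv(work_dir / "cluster" / "clusters_k2.tsv", sep="\t")
    report = groups.merge(refit, on="sample_id").merge(clusters, on="sample_id")
    best = pd.read_csv(work_dir / "survival" / "scan_best.tsv", sep="\t").iloc[0]
    report["above_best_cutoff"] = report["ca_fraction"] >= best["best_cutoff"]
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    write_manifest(out_dir, config, {"work_dir": work_dir}, "report")
    return out_dir / "report.tsv"
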