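"""Readers, writers, run configuration and the end-to-end pipeline.

On-disk formats are plain text: genotype TSV (rows = individuals, header =
SNP ids, cells 0/1/2 or NA), standard VCF (GT-based dosages via cyvcf2),
phenotype TSV (individual id column + one column per replicate), truth TSV,
posterior-summary TSV with a JSON metadata sidecar, ROC TSV and a JSON run
manifest that records everything needed to reproduce a run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GenotypeMatrix, PhenotypeSet, TruthTable
from .evaluate import (
    average_over_replicates,
    call_associated,
    rare_subset_roc,
    roc_curve,
)
from .exceptions import (
    AlignmentError,
    ConfigError,
    InvalidDataError,
    ParseError,
    UndefinedRocError,
)
from .model import ChainConfig, ModelData, PosteriorSummary, Priors, run_chain

__all__ = [
    "RunConfig",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_phenotypes",
    "write_phenotypes_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_roc_tsv",
    "run_pipeline",
]

log = logging.getLogger("bvsreg")

_VALID_CELLS = {"0", "1", "2", "NA"}


def setup_logging(verbosity: str = "INFO", logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def read_genotypes_tsv(path, transpose: bool = False) -> GenotypeMatrix:
    """Read a dosage TSV: individuals as rows, SNP ids in the header.

    Cells must be 0, 1, 2 or NA; NA is imputed to the column's mean
    observed dosage (logged).  ``transpose=True`` accepts SNP-major files.
    Malformed cells raise :class:`ParseError` naming the SNP and
    individual.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ParseError(f"{path}: duplicate SNP ids in header")
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.columns = header  # undo pandas' dedup mangling
    if transpose:
        df = df.T
    snp_ids = df.columns.to_numpy(dtype=object)
    indiv_ids = df.index.to_numpy(dtype=object)
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{path}: duplicate SNP ids in header")
    if len(set(indiv_ids)) != len(indiv_ids):
        raise ParseError(f"{path}: duplicate individual ids")
    values = df.to_numpy(dtype=object)
    bad = ~np.isin(values, list(_VALID_CELLS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid dosage {values[i, j]!r} at SNP "
            f"{snp_ids[j]!r}, individual {indiv_ids[i]!r} "
            "(expected 0, 1, 2 or NA)"
        )
    X = np.where(values == "NA", np.nan, values).astype(np.float64)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            raise ParseError(
                f"{path}: SNP {snp_ids[np.argmax(all_missing)]!r} has no "
                "observed dosages"
            )
        means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(means, idx[1])
        log.info("imputed %d missing dosages to column means in %s", n_missing, path)
    return GenotypeMatrix(X=X, snp_ids=snp_ids, individual_ids=indiv_ids)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        geno.X, index=geno.individual_ids, columns=geno.snp_ids
    )
    integral = np.isclose(df.to_numpy() % 1, 0).all()
    if integral:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic sites of a VCF as ALT-allele dosages.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing (NaN, imputed
    downstream).  Multi-allelic sites are skipped with a logged count.
    SNP ids come from the ID column, else CHROM:POS:REF:ALT.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    if len(samples) == 0:
        raise ParseError(f"{path}: VCF has no samples")
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(np.float64)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        ids.append(
            variant.ID
            or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        )
        cols.append(dosage)
    vcf.close()
    if not cols:
        raise ParseError(f"{path}: no usable biallelic sites")
    if n_multi:
        log.warning("skipped %d multi-allelic sites in %s", n_multi, path)
    geno = GenotypeMatrix(
        X=np.column_stack(cols),
        snp_ids=np.array(ids, dtype=object),
        individual_ids=samples,
    )
    geno.n_skipped_multiallelic = n_multi
    return geno


# --------------------------------------------------------------------------
# phenotypes / truth
# --------------------------------------------------------------------------

def read_phenotypes(path, individual_ids=None) -> PhenotypeSet:
    """Read a phenotype TSV (id column + one column per replicate).

    When ``individual_ids`` is given, rows are realigned to that order;
    individuals missing from the file raise :class:`AlignmentError` (no
    silent dropping).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no replicate columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric phenotype {bad.iloc[0]!r} in column "
                f"{col!r}, individual {bad.index[0]!r}"
            )
    if individual_ids is not None:
        wanted = list(individual_ids)
        missing = [i for i in wanted if i not in df.index]
        if missing:
            raise AlignmentError(
                f"{path}: individuals missing from phenotypes: {missing[:10]}"
            )
        df = df.loc[wanted]
    return PhenotypeSet(
        Y=df.to_numpy(dtype=np.float64),
        individual_ids=df.index.to_numpy(dtype=object),
        replicate_names=df.columns.to_numpy(dtype=object),
    )


def write_phenotypes_tsv(phenos: PhenotypeSet, path) -> None:
    df = pd.DataFrame(
        phenos.Y, index=phenos.individual_ids, columns=phenos.replicate_names
    )
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_truth_tsv(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"snp_id", "gene", "is_causal", "effect", "maf"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: truth table needs columns {sorted(required)}"
        )
    return TruthTable.from_dataframe(df)


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.to_dataframe().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# posterior summaries
# --------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_summary_tsv(summary: PosteriorSummary, path) -> None:
    """Write snp_id/ppa/alpha_mean TSV plus a JSON chain-metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "snp_id": summary.snp_ids,
            "ppa": summary.ppa,
            "alpha_mean": summary.alpha_mean,
        }
    ).to_csv(path, sep="\t", index=False)
    ks = np.asarray(summary.k_samples)
    meta = {
        "n_retained": summary.n_retained,
        "k_point": int(summary.k_point),
        "k_quantiles": {
            str(q): float(np.quantile(ks, q)) if ks.size else None
            for q in (0.025, 0.25, 0.5, 0.75, 0.975)
        },
        **summary.meta,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_summary_tsv(path) -> PosteriorSummary:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return PosteriorSummary(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        ppa=df["ppa"].to_numpy(dtype=float),
        alpha_mean=df["alpha_mean"].to_numpy(dtype=float),
        k_samples=np.array([], dtype=np.int64),
        k_point=int(meta.get("k_point", 0)),
        n_retained=int(meta.get("n_retained", 0)),
        meta=meta,
    )


def write_roc_tsv(roc, path) -> None:
    pd.DataFrame(
        {"cutoff": roc.cutoffs, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end run needs; mirrors the CLI flags."""

    genotypes: str
    phenotypes: str
    out_dir: str
    truth: str | None = None
    transpose_genotypes: bool = False
    n_iter: int = 15_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0
    v_eps: float = 10.0
    s_eps: float | None = None
    v_alpha: float = 4.0
    s_alpha: float | None = None
    a0: float = 1.0
    b0: float = 1.0
    expected_k: int = 10
    fix_pi: float | None = None
    fix_sigma2_eps: float | None = None
    fix_sigma2_alpha: float | None = None
    rare_maf_threshold: float = 0.01
    call_score: str = "both"
    max_replicates: int | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "genotypes" not in raw or "phenotypes" not in raw or "out_dir" not in raw:
            raise ConfigError("config requires genotypes, phenotypes and out_dir")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("genotypes", "phenotypes", "truth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def _priors_from_config(cfg: RunConfig) -> Priors:
    return Priors(
        s_alpha=cfg.s_alpha,
        v_alpha=cfg.v_alpha,
        s_eps=cfg.s_eps,
        v_eps=cfg.v_eps,
        a0=cfg.a0,
        b0=cfg.b0,
        expected_k=cfg.expected_k,
        fix_sigma2_eps=cfg.fix_sigma2_eps,
        fix_sigma2_alpha=cfg.fix_sigma2_alpha,
        fix_pi=cfg.fix_pi,
    )


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Per-replicate chain seed by fixed offset from the master seed."""
    return int((int(master_seed) + 1_000_003 * (replicate_index + 1)) % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Fit every replicate, average, call SNPs and (with truth) trace ROCs.

    Writes per-replicate summary TSVs, the averaged report, called-SNP
    table, ROC TSVs and AUC report when truth is available, and a JSON
    manifest sufficient to reproduce the run.  Returns the manifest.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(config.verbosity, out / "run.log")

    geno_path = Path(config.genotypes)
    if geno_path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        geno = read_genotypes_vcf(geno_path)
    else:
        geno = read_genotypes_tsv(geno_path, transpose=config.transpose_genotypes)
    phenos = read_phenotypes(config.phenotypes, individual_ids=geno.individual_ids)
    truth = read_truth_tsv(config.truth) if config.truth else None
    if truth is not None and (
        len(truth.snp_id) != geno.n_snps or (truth.snp_id != geno.snp_ids).any()
    ):
        raise AlignmentError("truth table SNPs do not match the genotype matrix")

    priors = _priors_from_config(config)
    n_rep = phenos.n_replicates
    if config.max_replicates is not None:
        n_rep = min(n_rep, config.max_replicates)

    summaries: list[PosteriorSummary] = []
    seeds: list[int] = []
    for r in range(n_rep):
        seed_r = replicate_seed(config.seed, r)
        seeds.append(seed_r)
        cfg = ChainConfig(
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=seed_r,
            thin=config.thin,
        )
        try:
            data = ModelData.from_genotypes(geno, phenos.replicate(r))
            summary = run_chain(data, priors, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"chain failed at stage 'fit', replicate {r + 1}: {exc}"
            ) from exc
        write_summary_tsv(summary, out / f"summary_rep{r + 1:03d}.tsv")
        summaries.append(summary)
        log.info("replicate %d/%d done (k_point=%d)", r + 1, n_rep, summary.k_point)

    avgs = average_over_replicates(summaries)
    called = call_associated(avgs, score=config.call_score)
    pd.DataFrame(
        {
            "snp_id": avgs.snp_ids,
            "mean_abs_coef": avgs.mean_abs_coef,
            "mean_ppa": avgs.mean_ppa,
            "rank_coef": avgs.rank_coef,
            "rank_ppa": avgs.rank_ppa,
            "called": called.called.astype(int),
        }
    ).to_csv(out / "averaged_report.tsv", sep="\t", index=False)

    auc_report: dict = {}
    if truth is not None:
        for score_name, scores in (
            ("coef", avgs.mean_abs_coef),
            ("ppa", avgs.mean_ppa),
        ):
            try:
                roc = roc_curve(scores, truth.is_causal)
                write_roc_tsv(roc, out / f"roc_all_{score_name}.tsv")
                auc_report[f"auc_all_{score_name}"] = roc.auc
            except UndefinedRocError as exc:
                log.warning("all-SNP ROC (%s) undefined: %s", score_name, exc)
            try:
                roc_rv = rare_subset_roc(
                    scores, truth, truth.maf, config.rare_maf_threshold
                )
                write_roc_tsv(roc_rv, out / f"roc_rare_{score_name}.tsv")
                auc_report[f"auc_rare_{score_name}"] = roc_rv.auc
            except UndefinedRocError as exc:
                log.warning("rare-only ROC (%s) undefined: %s", score_name, exc)
        if auc_report:
            (out / "auc_report.tsv").write_text(
                "metric\tvalue\n"
                + "".join(f"{k}\t{v:.6f}\n" for k, v in sorted(auc_report.items()))
            )

    manifest = {
        "package_version": __version__,
        "config": {
            k: getattr(config, k) for k in config.__dataclass_fields__
        },
        "replicate_seeds": seeds,
        "n_replicates_fit": n_rep,
        "k_range": list(called.k_range),
        "called_snps": list(called.called_ids),
        "auc": auc_report,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.glob("*.tsv")
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
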