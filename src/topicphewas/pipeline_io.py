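"""End-to-end pipeline orchestration and external formats.

Reads the four inputs (single-variant genotype dosages, subject x code
counts, per-subject covariates, optional code map), runs rollup ->
frequency filter -> LDA -> per-wave topic scan -> fixed-effects
meta-analysis -> Bonferroni selection -> individual-code follow-up for
significant topics, and writes the report tables and Manhattan-plot data.

All stages join subjects by id, never by row position: inputs are aligned
to the sorted intersection of subject ids, so shuffling input file rows
leaves every output byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import association, code_mapping, genotype_qc, meta_analysis, topic_model
from .code_mapping import CodeCountMatrix
from .synthetic_data import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_dosage_vcf",
    "read_dosage_tsv",
    "read_covariates",
    "read_counts_triplets",
    "read_counts_mtx",
    "manhattan_data",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``code_map`` may be a mapping-table path, ``"truncate"`` (roll ICD-9
    strings up to their 3-character stem) or ``None`` (use codes verbatim).
    """

    genotype: str
    counts: str
    covariates: str
    code_map: str | None = None
    n_topics: int = 50
    lda_alpha: float | None = None
    lda_beta: float = 0.1
    n_iterations: int = 500
    burn_in: int = 200
    thin: int = 10
    seed: int = 0
    min_prevalence: float = 0.005
    min_weight: float = 0.01
    weight_comparison: str = ">="
    min_cases: int = 10
    alpha: float = 0.05
    out_dir: str = "topicphewas_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve input paths relative to the config file
        for attr in ("genotype", "counts", "covariates"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(path.parent / p))
        if cfg.code_map and cfg.code_map != "truncate":
            p = Path(cfg.code_map)
            if not p.is_absolute():
                cfg.code_map = str(path.parent / p)
        return cfg


# ---------------------------------------------------------------------------
# readers


def read_dosage_vcf(path) -> pd.Series:
    """Dosage per subject from a single-variant VCF.

    The DS FORMAT field is used when present (fractional imputed dosages
    preserved); otherwise GT is converted to a minor-allele count.  Samples
    with missing calls are excluded with a log entry.  More or fewer than
    one variant record is a format error — the pipeline is single-locus.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    variants = [v for v in vcf]
    vcf.close()
    if len(variants) != 1:
        raise ValueError(
            f"{path}: expected exactly one variant record, found {len(variants)}"
        )
    var = variants[0]
    ds = var.format("DS")
    values: dict[str, float] = {}
    if ds is not None:
        ds = np.asarray(ds, float).ravel()
        for s, d in zip(samples, ds):
            if np.isnan(d):
                logger.info("read_dosage_vcf: sample %s missing DS, excluded", s)
                continue
            values[s] = float(d)
    else:
        for s, gt in zip(samples, var.genotypes):
            alleles = gt[:2]
            if any(a < 0 for a in alleles):
                logger.info("read_dosage_vcf: sample %s missing GT, excluded", s)
                continue
            values[s] = float(sum(1 for a in alleles if a > 0))
    return pd.Series(values, name="dosage")


def read_dosage_tsv(path) -> pd.Series:
    """Dosage per subject from a two-column TSV (subject_id, dosage)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return pd.Series(
        df["dosage"].to_numpy(float), index=df["subject_id"], name="dosage"
    )


def read_dosage(path) -> pd.Series:
    """Dispatch on extension: ``.vcf`` -> VCF reader, else TSV."""
    if str(path).endswith(".vcf") or str(path).endswith(".vcf.gz"):
        return read_dosage_vcf(path)
    return read_dosage_tsv(path)


def read_covariates(path) -> pd.DataFrame:
    """Covariates TSV: subject_id, wave, [dosage,] pc1..pcM, bmi."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "wave": str})
    required = {"subject_id", "wave", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariates file missing columns: {sorted(missing)}")
    return df


def read_counts_triplets(path) -> CodeCountMatrix:
    """Sparse triplet TSV (subject_id, code, count) -> count matrix.

    Rows and columns are ordered by first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "code": str})
    subjects = list(dict.fromkeys(df["subject_id"]))
    vocab = list(dict.fromkeys(df["code"]))
    si = {s: i for i, s in enumerate(subjects)}
    ci = {c: j for j, c in enumerate(vocab)}
    mat = sp.csr_matrix(
        (
            df["count"].to_numpy(np.int64),
            (df["subject_id"].map(si), df["code"].map(ci)),
        ),
        shape=(len(subjects), len(vocab)),
    )
    return CodeCountMatrix(subjects, vocab, mat)


def read_counts_mtx(path) -> CodeCountMatrix:
    """MatrixMarket counts with ``.rows``/``.cols`` index sidecar files."""
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(str(path)).astype(np.int64))
    rows = Path(str(path) + ".rows").read_text().splitlines()
    cols = Path(str(path) + ".cols").read_text().splitlines()
    return CodeCountMatrix(rows, cols, mat)


def read_counts(path) -> CodeCountMatrix:
    if str(path).endswith(".mtx"):
        return read_counts_mtx(path)
    return read_counts_triplets(path)


# ---------------------------------------------------------------------------
# report assembly


def manhattan_data(
    meta: list[meta_analysis.MetaResult], threshold: float
) -> pd.DataFrame:
    """Per-topic -log10 pooled p with the significance line value."""
    if not meta:
        raise ValueError("no meta-analysis results")
    rows = [
        {
            "topic": m.trait_id,
            "neg_log10_p": -np.log10(m.p),
            "above_threshold": bool(m.p < threshold),
            "threshold_line": -np.log10(threshold),
        }
        for m in meta
    ]
    return pd.DataFrame(rows)


def _assoc_frame(results: list[association.AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait_id": r.trait_id, "wave": r.wave, "n": r.n,
                "beta": r.beta, "se": r.se, "stat": r.stat, "p": r.p,
                "status": r.status, "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


def _meta_frame(metas: list[meta_analysis.MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait_id": m.trait_id, "n_waves_used": m.n_waves_used,
                "beta_pooled": m.beta_pooled, "se_pooled": m.se_pooled,
                "z": m.z, "p": m.p, "q_het": m.q_het, "df_het": m.df_het,
                "significant": m.significant,
            }
            for m in metas
        ]
    )


def _group_by_trait(results):
    groups: dict[str, list] = {}
    for r in results:
        groups.setdefault(r.trait_id, []).append(r)
    return groups


def build_report_table(
    codes: list[tuple[str, float]],
    presence_freq: dict[str, float],
    code_results: list[association.AssociationResult],
    code_results_bmi: list[association.AssociationResult],
    waves: list[str],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Follow-up table: one row per code with weight >= the follow-up cut.

    Columns mirror the study-style report: diagnosis label, pooled
    frequency, weight in topic, pooled p and OR, per-wave ORs, BMI-adjusted
    p and OR, and a blank external-annotation column.  Waves or codes too
    rare to fit are left as missing values.  Rows sort by pooled p
    ascending, codes without a pooled estimate last.
    """
    by_code = _group_by_trait(code_results)
    by_code_bmi = _group_by_trait(code_results_bmi)
    rows = []
    for code, weight in codes:
        row: dict = {
            "diagnosis": (labels or {}).get(code, code),
            "code": code,
            "frequency": presence_freq.get(code, np.nan),
            "weight_in_topic": weight,
        }
        per_wave = {r.wave: r for r in by_code.get(code, [])}
        usable = [r for r in per_wave.values() if r.status == "ok"]
        if usable:
            m = meta_analysis.fixed_effects_meta(usable)
            row["p"] = m.p
            row["or"] = m.odds_ratio
        else:
            row["p"] = np.nan
            row["or"] = np.nan
        for wave in waves:
            r = per_wave.get(wave)
            row[f"or_{wave}"] = (
                r.odds_ratio if r is not None and r.status == "ok" else np.nan
            )
        usable_bmi = [
            r for r in by_code_bmi.get(code, []) if r.status == "ok"
        ]
        if usable_bmi:
            mb = meta_analysis.fixed_effects_meta(usable_bmi)
            row["p_bmi_adjusted"] = mb.p
            row["or_bmi_adjusted"] = mb.odds_ratio
        else:
            row["p_bmi_adjusted"] = np.nan
            row["or_bmi_adjusted"] = np.nan
        row["external_annotation"] = ""
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["p", "code"], na_position="last", kind="stable"
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# orchestration


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write all outputs to ``config.out_dir``.

    Fixed seed and identical inputs give byte-identical outputs; any stage
    failure aborts with the stage name while retaining partial outputs and
    a MANIFEST marking the run incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log_fh = logging.FileHandler(out / "run.log", mode="w")
    log_fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("topicphewas").addHandler(log_fh)
    completed: list[str] = []
    manifest = {"complete": False, "stages": completed,
                "config": {k: v for k, v in asdict(config).items()}}

    def finish_stage(name: str) -> None:
        completed.append(name)
        with open(out / "MANIFEST.yaml", "w", newline="\n") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    stage = "load_inputs"
    try:
        dosage = read_dosage(config.genotype)
        cov = read_covariates(config.covariates)
        counts = read_counts(config.counts)

        ids = sorted(
            set(dosage.index) & set(cov["subject_id"]) & set(counts.subject_ids)
        )
        n_union = len(
            set(dosage.index) | set(cov["subject_id"]) | set(counts.subject_ids)
        )
        if n_union != len(ids):
            logger.info(
                "subject join: %d of %d ids common to all inputs; %d dropped",
                len(ids), n_union, n_union - len(ids),
            )
        if not ids:
            raise ValueError("no subject id common to genotype/counts/covariates")
        cov = cov.set_index("subject_id").loc[ids].reset_index()
        cov["dosage"] = dosage.loc[ids].to_numpy()
        cohort = CohortTable(cov)
        # canonical row/column order: outputs must not depend on input file order
        counts = counts.reorder_subjects(ids).sort_codes()
        logger.info("cohort: %d subjects, %d waves, %d raw codes",
                    cohort.n_subjects, len(cohort.waves), counts.n_codes)
        finish_stage(stage)

        stage = "genotype_qc"
        qc = {}
        for wave in cohort.waves:
            d = cohort.dosage()[cohort.wave_mask(wave)]
            gc = genotype_qc.counts_from_dosage(d)
            qc[wave] = {
                "n": int(gc.total),
                "maf": float(genotype_qc.minor_allele_frequency(gc)),
                "hwe_p": float(genotype_qc.hwe_test(gc)),
            }
        with open(out / "qc.yaml", "w", newline="\n") as fh:
            yaml.safe_dump(qc, fh, sort_keys=True)
        finish_stage(stage)

        stage = "map_codes"
        labels: dict[str, str] = {}
        if config.code_map == "truncate":
            cmap = code_mapping.truncation_map(counts.code_vocab)
            counts = code_mapping.map_codes(counts, cmap)
            labels = {e[1]: e[2] for e in cmap.entries}
        elif config.code_map:
            cmap = code_mapping.read_code_map(config.code_map)
            counts = code_mapping.map_codes(counts, cmap)
            labels = {e[1]: e[2] for e in cmap.entries}
        logger.info("after rollup: %d codes", counts.n_codes)
        finish_stage(stage)

        stage = "frequency_filter"
        counts, removed = code_mapping.frequency_filter(
            counts, config.min_prevalence
        )
        _write_tsv(pd.DataFrame({"removed_code": removed}),
                   out / "removed_codes.tsv")
        logger.info("after frequency filter: %d codes (%d removed)",
                    counts.n_codes, len(removed))
        finish_stage(stage)

        stage = "fit_lda"
        fit = topic_model.fit_lda(
            counts, n_topics=config.n_topics, alpha=config.lda_alpha,
            beta=config.lda_beta, n_iterations=config.n_iterations,
            burn_in=config.burn_in, thin=config.thin, seed=config.seed,
        )
        topic_model.save_fit(fit, out / "fit")
        finish_stage(stage)

        stage = "topic_scan"
        scores = topic_model.topic_scores(fit)
        wave_results = association.run_topic_scan(scores, cohort)
        _write_tsv(_assoc_frame(wave_results), out / "topic_wave_assoc.tsv")
        finish_stage(stage)

        stage = "meta_analysis"
        metas = [
            meta_analysis.fixed_effects_meta(group)
            for group in _group_by_trait(wave_results).values()
        ]
        threshold = meta_analysis.bonferroni_threshold(
            config.n_topics, config.alpha
        )
        significant = meta_analysis.select_significant_topics(metas, threshold)
        _write_tsv(_meta_frame(metas), out / "topic_meta.tsv")
        _write_tsv(manhattan_data(metas, threshold), out / "manhattan.tsv")
        logger.info("significant topics at p < %g: %s", threshold,
                    significant or "none")
        finish_stage(stage)

        stage = "code_followup"
        presence = counts.presence()
        freq = dict(zip(counts.code_vocab, presence.mean(axis=0)))
        report_frames = []
        all_code_results, all_code_results_bmi = [], []
        for trait in significant:
            k = int(trait.removeprefix("topic"))
            codes = topic_model.top_codes(
                fit, k, config.min_weight, config.weight_comparison
            )
            code_ids = [c for c, _ in codes]
            cols = [counts.code_vocab.index(c) for c in code_ids]
            pres = presence[:, cols]
            res = association.run_code_scan(
                pres, code_ids, cohort, adjust_bmi=False,
                min_cases=config.min_cases,
            )
            res_bmi = association.run_code_scan(
                pres, code_ids, cohort, adjust_bmi=True,
                min_cases=config.min_cases,
            )
            all_code_results.extend(res)
            all_code_results_bmi.extend(res_bmi)
            table = build_report_table(
                codes, freq, res, res_bmi, cohort.waves, labels
            )
            table.insert(0, "topic", trait)
            report_frames.append(table)
        if report_frames:
            report = pd.concat(report_frames, ignore_index=True)
        else:
            report = build_report_table([], {}, [], [], cohort.waves)
            report.insert(0, "topic", pd.Series(dtype=str))
        _write_tsv(report, out / "report.tsv")
        _write_tsv(_assoc_frame(all_code_results), out / "code_wave_assoc.tsv")
        _write_tsv(_assoc_frame(all_code_results_bmi),
                   out / "code_wave_assoc_bmi.tsv")
        finish_stage(stage)

        manifest["complete"] = True
        manifest["n_subjects"] = cohort.n_subjects
        manifest["n_codes_modelled"] = counts.n_codes
        manifest["bonferroni_threshold"] = threshold
        manifest["significant_topics"] = list(significant)
        with open(out / "MANIFEST.yaml", "w", newline="\n") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    except PipelineError:
        raise
    except Exception as exc:
        with open(out / "MANIFEST.yaml", "w", newline="\n") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise PipelineError(stage, exc) from exc
    finally:
        logging.getLogger("topicphewas").removeHandler(log_fh)
        log_fh.close()
    return out
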