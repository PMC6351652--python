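"""Synthetic genotype + EHR cohort generator.

Emulates, at configurable scale, the structure of a multi-wave biobank
cohort genotyped at a single biallelic variant: four genotyping waves,
hard-call dosages in Hardy-Weinberg proportions at a given minor allele
frequency, principal-component covariates, BMI correlated with genotype,
and per-subject diagnostic code counts drawn from the latent Dirichlet
allocation (LDA) generative model with a planted additive genotype effect
on one topic's Dirichlet concentration.

Because the code counts are drawn from exactly the model family the
downstream topic model assumes, parameter recovery is a fair test surface:
the generator returns the true topic-code distributions (phi), the true
per-subject topic weights (theta) and the planted effect alongside the
count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .code_mapping import CodeCountMatrix

__all__ = [
    "SimulationConfig",
    "CohortTable",
    "TrueParameters",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_topic_weights",
    "simulate_code_counts",
    "write_cohort",
]

#: default wave sizes, one tenth of the study's four genotyping waves
DEFAULT_WAVE_SIZES = (360, 333, 355, 310)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 1/10-scale four-wave cohort at minor allele
    frequency 0.079 with 20 latent disease topics over a vocabulary of 200
    codes.  ``effect_size`` is the additive per-allele shift applied to the
    risk topic's Dirichlet concentration (0 = global null).
    """

    n_subjects_per_wave: tuple[int, ...] = DEFAULT_WAVE_SIZES
    maf: float = 0.079
    n_topics_true: int = 20
    n_codes: int = 200
    alpha0: float = 0.3
    beta_phi: float = 0.05
    effect_size: float = 1.0
    risk_topic_index: int = 0
    codes_per_subject_mean: float = 30.0
    bmi_mean: float = 27.6
    bmi_sd: float = 6.1
    bmi_genotype_slope: float = 0.3
    n_pcs: int = 10
    dosage_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_subjects_per_wave = tuple(int(n) for n in self.n_subjects_per_wave)
        if any(n < 2 for n in self.n_subjects_per_wave):
            raise ValueError("every wave must have at least 2 subjects")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.n_topics_true < 1:
            raise ValueError("n_topics_true must be positive")
        if self.n_codes < 1:
            raise ValueError("n_codes must be positive")
        if self.alpha0 <= 0 or self.beta_phi <= 0:
            raise ValueError("Dirichlet concentrations must be strictly positive")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0 <= self.risk_topic_index < self.n_topics_true:
            raise ValueError(
                f"risk_topic_index {self.risk_topic_index} out of range "
                f"for {self.n_topics_true} topics"
            )
        if self.codes_per_subject_mean <= 0:
            raise ValueError("codes_per_subject_mean must be positive")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be nonnegative")
        if self.dosage_noise_sd < 0:
            raise ValueError("dosage_noise_sd must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_wave)

    @property
    def wave_labels(self) -> list[str]:
        return [f"wave{i + 1}" for i in range(len(self.n_subjects_per_wave))]


@dataclass
class CohortTable:
    """Subjects with wave label, allele dosage, PC covariates and BMI.

    Backed by a DataFrame with columns ``subject_id``, ``wave``, ``dosage``,
    ``pc1..pcM``, ``bmi``.  Subject ids must be unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "wave", "dosage", "bmi"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.df["subject_id"].duplicated().any():
            raise ValueError("subject_id must be unique within the cohort")
        d = self.df["dosage"].to_numpy(float)
        if np.any((d < 0) | (d > 2)):
            raise ValueError("dosage must lie in [0, 2]")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def waves(self) -> list[str]:
        return sorted(self.df["wave"].unique())

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("pc")]

    def dosage(self) -> np.ndarray:
        return self.df["dosage"].to_numpy(float)

    def pcs(self) -> np.ndarray:
        return self.df[self.pc_columns].to_numpy(float)

    def bmi(self) -> np.ndarray:
        return self.df["bmi"].to_numpy(float)

    def wave_mask(self, wave: str) -> np.ndarray:
        return (self.df["wave"] == wave).to_numpy()

    def sort_by_id(self) -> "CohortTable":
        return CohortTable(self.df.sort_values("subject_id", kind="stable"))


@dataclass
class TrueParameters:
    """Ground truth of one simulated cohort, for recovery testing."""

    phi: np.ndarray          # K_true x V, row-stochastic
    theta: np.ndarray        # N x K_true, row-stochastic
    doc_lengths: np.ndarray  # N, token count per subject
    risk_topic_index: int
    effect_size: float


def simulate_genotypes(n: int, maf: float, seed: int) -> np.ndarray:
    """Draw ``n`` hard-call dosages as Binomial(2, maf) — Hardy-Weinberg
    proportions at the given minor allele frequency."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(np.int64)


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate the cohort covariate table: waves, genotypes, PCs, BMI.

    PCs are independent standard normals (no confounding).  BMI is
    Normal(bmi_mean + bmi_genotype_slope * dosage, bmi_sd).  When
    ``dosage_noise_sd > 0``, fractional dosages are produced by adding
    Gaussian noise to the hard calls and clipping to [0, 2], emulating
    imputed dosages.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for wave, n in zip(config.wave_labels, config.n_subjects_per_wave):
        geno = rng.binomial(2, config.maf, size=n).astype(float)
        dosage = geno
        if config.dosage_noise_sd > 0:
            dosage = np.clip(
                geno + rng.normal(0.0, config.dosage_noise_sd, size=n), 0.0, 2.0
            )
        pcs = rng.standard_normal((n, config.n_pcs))
        bmi = rng.normal(
            config.bmi_mean + config.bmi_genotype_slope * geno, config.bmi_sd
        )
        data = {
            "subject_id": [f"S{offset + i:06d}" for i in range(n)],
            "wave": wave,
            "dosage": dosage,
        }
        for j in range(config.n_pcs):
            data[f"pc{j + 1}"] = pcs[:, j]
        data["bmi"] = bmi
        frames.append(pd.DataFrame(data))
        offset += n
    return CohortTable(pd.concat(frames, ignore_index=True))


def simulate_topic_weights(
    cohort: CohortTable, config: SimulationConfig, rng=None
) -> np.ndarray:
    """Draw true per-subject topic weights with the planted genotype effect.

    For subject i with dosage d_i, theta_i ~ Dirichlet(alpha_i) where
    alpha_i[k] = alpha0 for every topic except the risk topic, whose
    concentration is alpha0 + effect_size * d_i (additive per allele, so
    the Dirichlet mean of the risk topic rises with each minor allele).
    """
    if cohort.n_subjects == 0:
        raise ValueError("cohort is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    K = config.n_topics_true
    alpha = np.full((cohort.n_subjects, K), config.alpha0)
    alpha[:, config.risk_topic_index] += config.effect_size * cohort.dosage()
    # Dirichlet via normalized gammas (vectorized over subjects)
    gam = rng.gamma(shape=alpha)
    return gam / gam.sum(axis=1, keepdims=True)


def simulate_code_counts(
    cohort: CohortTable, config: SimulationConfig
) -> tuple[CodeCountMatrix, TrueParameters]:
    """Draw diagnostic code counts from the LDA generative model.

    For each topic k, phi_k ~ Dirichlet(beta_phi * 1_V).  Per-subject topic
    weights theta come from :func:`simulate_topic_weights` (genotype-shifted
    Dirichlet).  Document length L_i ~ max(1, Poisson(codes_per_subject_mean));
    each of the L_i tokens draws a topic from theta_i then a code from phi of
    that topic.
    """
    if cohort.n_subjects == 0:
        raise ValueError("cohort is empty")
    if config.effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    K, V = config.n_topics_true, config.n_codes
    N = cohort.n_subjects

    phi = rng.dirichlet(np.full(V, config.beta_phi), size=K)
    theta = simulate_topic_weights(cohort, config, rng)

    lengths = np.maximum(1, rng.poisson(config.codes_per_subject_mean, size=N))
    vocab = [f"{400 + v // 10}.{v % 10}" for v in range(V)]

    rows, cols, vals = [], [], []
    for i in range(N):
        z = rng.choice(K, size=lengths[i], p=theta[i])
        topic_counts = np.bincount(z, minlength=K)
        row_counts = np.zeros(V, dtype=np.int64)
        for k in np.nonzero(topic_counts)[0]:
            w = rng.choice(V, size=topic_counts[k], p=phi[k])
            row_counts += np.bincount(w, minlength=V)
        nz = np.nonzero(row_counts)[0]
        rows.extend([i] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(row_counts[nz].tolist())
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(N, V), dtype=np.int64
    )
    matrix = CodeCountMatrix(cohort.subject_ids, vocab, counts)
    truth = TrueParameters(
        phi=phi,
        theta=theta,
        doc_lengths=lengths.astype(np.int64),
        risk_topic_index=config.risk_topic_index,
        effect_size=config.effect_size,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# on-disk emission

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=4>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage (minor allele count)">
"""


def _format_ds(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def write_cohort(cohort: CohortTable, counts: CodeCountMatrix, directory) -> dict:
    """Write the cohort to ``directory`` in the pipeline's input formats.

    Emits the dosage both as a minimal single-variant VCF (DS FORMAT field)
    and as TSV; the counts both as a sparse triplet TSV and as MatrixMarket
    + row/column index sidecars; and the covariates as TSV.  All files are
    UTF-8 with LF line endings and round-trip through the readers in
    :mod:`topicphewas.pipeline_io`.

    Returns a dict of the written paths.
    """
    from pathlib import Path

    if cohort.n_subjects == 0:
        raise ValueError("cohort is empty")
    if counts.subject_ids != cohort.subject_ids:
        raise ValueError("counts and cohort subject ids differ")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    ids = cohort.subject_ids
    dosage = cohort.dosage()

    # VCF: one variant record with GT (rounded hard call) and DS (exact)
    vcf = directory / "dosage.vcf"
    with open(vcf, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        fields = []
        for d in dosage:
            hard = int(round(d))
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
            fields.append(f"{gt}:{_format_ds(d)}")
        fh.write(
            "4\t103188709\tvar1\tC\tT\t.\tPASS\t.\tGT:DS\t"
            + "\t".join(fields) + "\n"
        )
    paths["vcf"] = vcf

    dosage_tsv = directory / "dosage.tsv"
    with open(dosage_tsv, "w", newline="\n") as fh:
        fh.write("subject_id\tdosage\n")
        for s, d in zip(ids, dosage):
            fh.write(f"{s}\t{_format_ds(d)}\n")
    paths["dosage_tsv"] = dosage_tsv

    # covariates
    cov_tsv = directory / "covariates.tsv"
    cohort.df.to_csv(cov_tsv, sep="\t", index=False, lineterminator="\n")
    paths["covariates"] = cov_tsv

    # counts: triplet TSV
    trip = directory / "counts_triplets.tsv"
    coo = counts.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(trip, "w", newline="\n") as fh:
        fh.write("subject_id\tcode\tcount\n")
        for k in order:
            fh.write(
                f"{counts.subject_ids[coo.row[k]]}\t"
                f"{counts.code_vocab[coo.col[k]]}\t{coo.data[k]}\n"
            )
    paths["triplets"] = trip

    # counts: MatrixMarket + index sidecars
    import scipy.io

    mtx = directory / "counts.mtx"
    scipy.io.mmwrite(str(mtx), counts.counts, field="integer")
    with open(directory / "counts.mtx.rows", "w", newline="\n") as fh:
        fh.write("\n".join(counts.subject_ids) + "\n")
    with open(directory / "counts.mtx.cols", "w", newline="\n") as fh:
        fh.write("\n".join(counts.code_vocab) + "\n")
    paths["mtx"] = mtx
    return paths
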