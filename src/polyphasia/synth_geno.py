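"""Synthetic case/control genotype matrices and trios with planted truth.

The study's exomes (Epi25 / family trios) are access-controlled, so the
genetic modules are exercised on simulations. Genotypes are drawn under
Hardy–Weinberg and linkage equilibrium — sufficient to exercise the
odds-ratio / LOOCV mechanics, which themselves ignore LD. Case/control
phenotypes come from a logistic model over planted per-allele log-odds
effects, with the intercept calibrated by bisection so the expected number
of cases matches the configured split; whole cohorts are resampled until
the realised split is exact, mirroring the study's fixed 16/14 design.

Trios plant exactly one variant (or pair) satisfying a named inheritance
scenario; background variants are Mendelian-consistent and rejection-sampled
so that none of them satisfies that scenario, making the planted set an
exact recovery oracle for the trio filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (GenotypeMatrix, Pedigree, Person, VariantRecord,
                         write_annotations, write_ped, write_vcf)

_SCENARIO_GENO = {
    # scenario: (child, father, mother, father_affected, mother_affected)
    "autosomal_dominant": (1, 1, 0, True, False),
    "autosomal_recessive": (2, 1, 1, False, False),
    "de_novo": (1, 0, 0, False, False),
    "x_linked": (1, 0, 1, False, False),
}


@dataclass(frozen=True)
class GenoSimConfig:
    """Case/control simulation settings; defaults mirror the 16/14 design."""

    n_cases: int = 16
    n_controls: int = 14
    n_variants: int = 100
    planted: tuple[tuple[int, float], ...] = ()   # (variant index, log-OR)
    af_low: float = 0.05
    af_high: float = 0.5
    missing_rate: float = 0.0
    max_retries: int = 10_000

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_variants <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        for j, beta in self.planted:
            if not (0 <= j < self.n_variants and np.isfinite(beta)):
                raise ValueError(f"bad planted effect ({j}, {beta})")


def _calibrate_intercept(counts: np.ndarray, betas: np.ndarray,
                         target_cases: int) -> float:
    """Bisection on the intercept so that E[#cases] = target."""
    eta = counts @ betas

    def expected(b0: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(-(eta + b0)))))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expected(mid) < target_cases:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_case_control(config: GenoSimConfig | None = None,
                          seed: int = 0) -> tuple[GenotypeMatrix, dict]:
    """Simulate a fixed-split case/control genotype matrix.

    Returns the matrix (phenotype attached) and a truth record holding the
    planted effects, calibrated intercept and generating allele frequencies.
    Raises after ``max_retries`` resamples if the exact split is unattainable.
    """
    config = config or GenoSimConfig()
    rng = np.random.default_rng(seed)
    n = config.n_cases + config.n_controls
    afs = rng.uniform(config.af_low, config.af_high, size=config.n_variants)
    betas = np.zeros(config.n_variants)
    for j, beta in config.planted:
        betas[j] = beta

    for _ in range(config.max_retries):
        counts = rng.binomial(2, afs, size=(n, config.n_variants)).astype(float)
        b0 = _calibrate_intercept(counts, betas, config.n_cases)
        p = 1.0 / (1.0 + np.exp(-(counts @ betas + b0)))
        pheno = rng.random(n) < p
        if int(pheno.sum()) == config.n_cases:
            break
    else:
        raise RuntimeError(
            f"could not realise a {config.n_cases}/{config.n_controls} split "
            f"in {config.max_retries} attempts; planted effects too extreme?")

    if config.missing_rate > 0:
        mask = rng.random(counts.shape) < config.missing_rate
        counts[mask] = np.nan

    # cases first, stable within class, so sample order is deterministic
    order = np.concatenate([np.flatnonzero(pheno), np.flatnonzero(~pheno)])
    counts = counts[order]
    pheno = pheno[order]

    variants = [VariantRecord(chrom=str(1 + j % 22), pos=1_000 + j,
                              ref="A", alt="G", gene=f"GENE{j:04d}")
                for j in range(config.n_variants)]
    sample_ids = [f"Sample_{i + 1}" for i in range(n)]
    matrix = GenotypeMatrix(sample_ids=sample_ids, variants=variants,
                            counts=counts, phenotype=pheno)
    truth = {"planted": list(config.planted), "intercept": b0,
             "allele_freqs": afs.tolist()}
    return matrix, truth


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

def _transmit(parent: int, rng: np.random.Generator) -> int:
    """Number of alt alleles in one gamete from a diploid parent."""
    if parent == 0:
        return 0
    if parent == 2:
        return 1
    return int(rng.random() < 0.5)


def _satisfies(scenario: str, c: int, f: int, m: int,
               father_affected: bool, mother_affected: bool) -> bool:
    """Does an autosomal background genotype combo satisfy the scenario?"""
    if scenario == "autosomal_dominant":
        ok = c >= 1 and (father_affected or mother_affected)
        ok = ok and ((f >= 1) if father_affected else (f == 0))
        ok = ok and ((m >= 1) if mother_affected else (m == 0))
        return bool(ok)
    if scenario == "autosomal_recessive":
        return c == 2 and f == 1 and m == 1
    if scenario == "de_novo":
        return c >= 1 and f == 0 and m == 0
    # x_linked and compound_het cannot fire on autosomal singleton genes
    return False


def simulate_trio(scenario: str, n_background_variants: int = 50,
                  seed: int = 0, background_af: float = 0.2,
                  out_prefix: str | None = None):
    """Simulate one trio with a planted scenario variant.

    Background variants sit on autosomes in singleton genes, are drawn from
    Hardy–Weinberg parents with Mendelian transmission to the child, and are
    rejection-resampled whenever the sampled combination would itself satisfy
    the target scenario (so planted-set recovery is exact). Phenotypes are
    polyphasia: the child is always affected; parental status follows the
    scenario.

    Returns ``(trio, truth)`` where ``truth["planted_keys"]`` lists the
    planted variant key(s). With ``out_prefix``, also writes
    ``<prefix>.vcf``, ``<prefix>.ped``, ``<prefix>.annotations.tsv``.
    """
    from .trio_filter import SCENARIOS, TrioGenotypes

    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)

    if scenario == "compound_het":
        father_affected = mother_affected = False
        child_sex = "male"
        planted = [
            (VariantRecord(chrom="2", pos=500_000, ref="C", alt="T",
                           impact="MEDIUM", region="coding_exonic",
                           gene="GENE_CH"), 1, 1, 0),
            (VariantRecord(chrom="2", pos=500_100, ref="G", alt="A",
                           impact="MEDIUM", region="coding_exonic",
                           gene="GENE_CH"), 1, 0, 1),
        ]
    elif scenario == "x_linked":
        c, f, m, father_affected, mother_affected = _SCENARIO_GENO[scenario]
        child_sex = "male"
        planted = [(VariantRecord(chrom="X", pos=500_000, ref="C", alt="T",
                                  impact="MEDIUM", region="coding_exonic",
                                  gene="GENE_X"), c, f, m)]
    else:
        c, f, m, father_affected, mother_affected = _SCENARIO_GENO[scenario]
        child_sex = "female"
        planted = [(VariantRecord(chrom="2", pos=500_000, ref="C", alt="T",
                                  impact="MEDIUM", region="coding_exonic",
                                  gene="GENE_P"), c, f, m)]

    variants: list[VariantRecord] = []
    child_g: list[int] = []
    father_g: list[int] = []
    mother_g: list[int] = []

    for j in range(n_background_variants):
        while True:
            f_gt = int(rng.binomial(2, background_af))
            m_gt = int(rng.binomial(2, background_af))
            c_gt = _transmit(f_gt, rng) + _transmit(m_gt, rng)
            if not _satisfies(scenario, c_gt, f_gt, m_gt,
                              father_affected, mother_affected):
                break
        variants.append(VariantRecord(
            chrom=str(1 + (j % 22)), pos=10_000 + j * 100, ref="A", alt="G",
            impact="MEDIUM", region="coding_exonic", gene=f"BG{j:04d}"))
        father_g.append(f_gt)
        mother_g.append(m_gt)
        child_g.append(c_gt)

    for rec, c_gt, f_gt, m_gt in planted:
        variants.append(rec)
        child_g.append(c_gt)
        father_g.append(f_gt)
        mother_g.append(m_gt)

    trio = TrioGenotypes(
        family_id="FAM1", child_id="child", father_id="father",
        mother_id="mother", variants=tuple(variants),
        child=np.array(child_g, dtype=float),
        father=np.array(father_g, dtype=float),
        mother=np.array(mother_g, dtype=float),
        child_affected=True, father_affected=father_affected,
        mother_affected=mother_affected, child_sex=child_sex)
    truth = {"scenario": scenario,
             "planted_keys": [rec.key for rec, *_ in planted]}

    if out_prefix is not None:
        matrix = GenotypeMatrix(
            sample_ids=["child", "father", "mother"], variants=variants,
            counts=np.array([child_g, father_g, mother_g], dtype=float))
        write_vcf(matrix, f"{out_prefix}.vcf")
        write_annotations(variants, f"{out_prefix}.annotations.tsv")
        ped = Pedigree(families={"FAM1": {
            "father": Person("father", None, None, "male", father_affected),
            "mother": Person("mother", None, None, "female", mother_affected),
            "child": Person("child", "father", "mother", child_sex, True),
        }})
        write_ped(ped, f"{out_prefix}.ped")
    return trio, truth
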