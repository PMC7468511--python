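"""Trio-based variant prioritisation for the polyphasic phenotype.

A proband-father-mother trio is screened under one of five inheritance
scenarios — autosomal dominant, autosomal recessive, de novo, compound
heterozygous, X-linked — where "affected" means *polyphasic* (the phenotype
segregating in the families, which includes parents who are polyphasic
without being epileptic). Around the segregation test sit the standard
rarity filters (reference-panel MAF, functional impact, coding region) and
an exclusion step against an unrelated control cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)

SCENARIOS = ("autosomal_dominant", "autosomal_recessive", "de_novo",
             "compound_het", "x_linked")

_X_NAMES = {"X", "chrX", "x", "chrx", "23"}


@dataclass(frozen=True)
class TrioGenotypes:
    """Allele counts and polyphasia status for one child-father-mother trio."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    variants: tuple[VariantRecord, ...]
    child: np.ndarray    # alt-allele counts, NaN = missing
    father: np.ndarray
    mother: np.ndarray
    child_affected: bool = True
    father_affected: bool = False
    mother_affected: bool = False
    child_sex: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("child", "father", "mother"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(self.variants),):
                raise ValueError(f"{name} genotype vector length mismatch")

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix, family_id: str,
                    child_id: str, father_id: str, mother_id: str,
                    **kwargs) -> "TrioGenotypes":
        ids = matrix.sample_ids
        for sid in (child_id, father_id, mother_id):
            if sid not in ids:
                raise ValueError(f"sample {sid!r} not in genotype matrix")
        return cls(
            family_id=family_id, child_id=child_id, father_id=father_id,
            mother_id=mother_id, variants=tuple(matrix.variants),
            child=matrix.counts[ids.index(child_id)],
            father=matrix.counts[ids.index(father_id)],
            mother=matrix.counts[ids.index(mother_id)],
            **kwargs)


@dataclass(frozen=True)
class FilterConfig:
    """Rarity/functional filter settings (defaults mirror the study)."""

    maf_max: float = 0.01
    keep_impacts: frozenset = frozenset({"HIGH", "MEDIUM"})
    keep_regions: frozenset = frozenset({"coding_exonic"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_max <= 1.0:
            raise ValueError("maf_max must lie in [0, 1]")
        if not self.keep_impacts or not self.keep_regions:
            raise ValueError("keep sets must be non-empty")
        object.__setattr__(self, "keep_impacts", frozenset(self.keep_impacts))
        object.__setattr__(self, "keep_regions", frozenset(self.keep_regions))


def annotation_filter(variants: list[VariantRecord],
                      config: FilterConfig | None = None) -> list[VariantRecord]:
    """Rare + impactful + coding filter.

    A variant survives when every *present* reference MAF is ≤ ``maf_max``
    (variants with no MAF at all are novel and pass), its impact is in
    ``keep_impacts`` and its region is in ``keep_regions``. Idempotent.
    """
    config = config or FilterConfig()
    out = []
    for v in variants:
        if any(m > config.maf_max for m in v.mafs()):
            continue
        if v.impact not in config.keep_impacts:
            continue
        if v.region not in config.keep_regions:
            continue
        out.append(v)
    return out


def _is_x(chrom: str) -> bool:
    return chrom in _X_NAMES


def scenario_filter(trio: TrioGenotypes, scenario: str,
                    variants: list[VariantRecord] | None = None
                    ) -> list[VariantRecord]:
    """Variants segregating with polyphasia under the named scenario.

    Variants with a missing genotype in any trio member are skipped (logged).
    ``compound_het`` returns the union of all gene-grouped valid pairs; use
    :func:`compound_het_pairs` for the pairs themselves.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if variants is None:
        variants = list(trio.variants)
    index = {v.key: j for j, v in enumerate(trio.variants)}

    if scenario == "compound_het":
        pairs = compound_het_pairs(trio, variants)
        seen: dict[str, VariantRecord] = {}
        for _gene, v1, v2 in pairs:
            seen.setdefault(v1.key, v1)
            seen.setdefault(v2.key, v2)
        return list(seen.values())

    out = []
    for v in variants:
        j = index[v.key]
        c, f, m = trio.child[j], trio.father[j], trio.mother[j]
        if np.isnan(c) or np.isnan(f) or np.isnan(m):
            logger.info("variant %s skipped for %s: missing genotype",
                        v.key, scenario)
            continue
        if scenario == "autosomal_dominant":
            # inherited: carried by the polyphasic child and every polyphasic
            # parent, absent from every non-polyphasic parent; at least one
            # affected parent must transmit (otherwise the variant is de novo,
            # not dominant)
            ok = c >= 1 and (trio.father_affected or trio.mother_affected)
            for count, affected in ((f, trio.father_affected),
                                    (m, trio.mother_affected)):
                ok = ok and ((count >= 1) if affected else (count == 0))
        elif scenario == "autosomal_recessive":
            ok = c == 2 and f == 1 and m == 1
        elif scenario == "de_novo":
            ok = c >= 1 and f == 0 and m == 0
        elif scenario == "x_linked":
            if not _is_x(v.chrom):
                ok = False
            elif trio.child_sex == "male":
                # hemizygous males may be coded 1 or 2
                ok = c >= 1 and m >= 1
            else:
                ok = c == 2 and f >= 1 and m >= 1
        else:  # pragma: no cover
            raise AssertionError(scenario)
        if ok:
            out.append(v)
    return out


def compound_het_pairs(trio: TrioGenotypes,
                       variants: list[VariantRecord] | None = None
                       ) -> list[tuple[str, VariantRecord, VariantRecord]]:
    """Gene-grouped compound-heterozygous pairs.

    Both variants must be heterozygous in the child with unambiguous and
    opposite parental origin (one paternal-only, one maternal-only); phase
    is inferred from parental genotypes, not reads.
    """
    if variants is None:
        variants = list(trio.variants)
    index = {v.key: j for j, v in enumerate(trio.variants)}

    by_gene: dict[str, list[tuple[VariantRecord, str]]] = {}
    for v in variants:
        j = index[v.key]
        c, f, m = trio.child[j], trio.father[j], trio.mother[j]
        if np.isnan(c) or np.isnan(f) or np.isnan(m):
            logger.info("variant %s skipped for compound_het: missing genotype",
                        v.key)
            continue
        if c != 1:
            continue
        # unambiguous origin: exactly one parent carries the allele
        if f >= 1 and m == 0:
            origin = "paternal"
        elif m >= 1 and f == 0:
            origin = "maternal"
        else:
            continue
        gene = v.gene if v.gene is not None else f"__singleton__{v.key}"
        by_gene.setdefault(gene, []).append((v, origin))

    pairs = []
    for gene, entries in by_gene.items():
        paternal = [v for v, o in entries if o == "paternal"]
        maternal = [v for v, o in entries if o == "maternal"]
        for vp in paternal:
            for vm in maternal:
                pairs.append((gene, vp, vm))
    return pairs


def exclude_in_controls(variants: list[VariantRecord],
                        control_matrix: GenotypeMatrix) -> list[VariantRecord]:
    """Drop any candidate carried (alt count ≥ 1) by any control sample."""
    carried = set()
    for j, v in enumerate(control_matrix.variants):
        col = control_matrix.counts[:, j]
        if np.nansum(col > 0) >= 1:
            carried.add(v.key)
    kept = [v for v in variants if v.key not in carried]
    dropped = len(variants) - len(kept)
    if dropped:
        logger.info("excluded %d candidate(s) present in controls", dropped)
    return kept


def run_trio_analysis(trio: TrioGenotypes, scenario: str,
                      config: FilterConfig | None = None,
                      control_matrix: GenotypeMatrix | None = None
                      ) -> list[VariantRecord]:
    """annotation filter → scenario segregation → control exclusion."""
    candidates = annotation_filter(list(trio.variants), config)
    candidates = scenario_filter(trio, scenario, candidates)
    if control_matrix is not None:
        candidates = exclude_in_controls(candidates, control_matrix)
    return candidates
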