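"""Readers and writers for the package's on-disk formats.

The MEP trace table is a long-format TSV (one row per sample point) so
fixtures stay diffable; genotypes come in as VCF 4.2 plus a sidecar
annotation TSV keyed by ``chrom:pos:ref:alt``; pedigrees are standard
6-column PED with the affected column encoding the *polyphasia* phenotype
(2 = polyphasic, 1 = non-polyphasic, 0/-9 = unknown).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GROUPS = ("patient", "relative", "control")
SITES = ("cortex", "spinal_cervical", "spinal_lumbar")
MUSCLES = ("ADM", "TA")
SIDES = ("left", "right")
IMPACTS = ("HIGH", "MEDIUM", "LOW", "MODIFIER")
REGIONS = ("coding_exonic", "intronic", "other")

#: VEP says MODERATE where VarApp-style tables say MEDIUM.
_IMPACT_SYNONYMS = {"MODERATE": "MEDIUM"}

MEP_TSV_COLUMNS = (
    "subject_id", "group", "site", "muscle", "side", "trace_id",
    "sampling_rate_hz", "stimulus_index", "sample_index", "amplitude_mv",
)

ANNOTATION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "consequence", "impact", "region",
    "maf_1000g", "maf_esp", "maf_exac",
)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# MEP traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MEPTrace:
    """One stimulation's EMG waveform plus its recording metadata.

    ``samples`` are amplitudes in mV; ``stimulus_index`` marks time zero
    (the TMS pulse) within ``samples``.
    """

    subject_id: str
    group: str
    site: str
    muscle: str
    side: str
    trace_id: str
    sampling_rate: float
    stimulus_index: int
    samples: np.ndarray

    #: minimum post-stimulus span the analysis window needs, in ms
    MIN_POST_MS = 45.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not 0 <= self.stimulus_index < samples.size:
            raise ValueError("stimulus_index outside sample range")
        post_ms = (samples.size - 1 - self.stimulus_index) / self.sampling_rate * 1e3
        if post_ms < self.MIN_POST_MS:
            raise ValueError(
                f"trace holds only {post_ms:.1f} ms after the stimulus; "
                f"≥ {self.MIN_POST_MS} ms needed for the analysis window"
            )

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        idx = np.arange(self.samples.size) - self.stimulus_index
        return idx / self.sampling_rate * 1e3

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MEPTrace):
            return NotImplemented
        return (
            (self.subject_id, self.group, self.site, self.muscle, self.side,
             self.trace_id, self.sampling_rate, self.stimulus_index)
            == (other.subject_id, other.group, other.site, other.muscle,
                other.side, other.trace_id, other.sampling_rate,
                other.stimulus_index)
            and np.array_equal(self.samples, other.samples)
        )


def _norm_enum(value: str, allowed: Sequence[str], what: str) -> str:
    v = str(value).strip()
    for cand in allowed:
        if v.lower() == cand.lower():
            return cand
    raise FormatError(f"unrecognised {what} value {value!r}; expected one of {allowed}")


def read_mep_table(path: str | Path) -> list[MEPTrace]:
    """Read the long-format MEP TSV into a list of traces.

    One trace per (subject_id, trace_id) block, samples ordered by
    ``sample_index``. Enum columns are matched case-insensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    missing = [c for c in MEP_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    try:
        # builtin float() is correctly rounded; pandas' fast parser is not,
        # and the round trip must be bit-exact
        amp = df["amplitude_mv"].map(float)
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["amplitude_mv"], errors="coerce").isna()
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"{path}: non-numeric amplitude_mv at line {line}") from None
    df = df.assign(amplitude_mv=amp,
                   sample_index=pd.to_numeric(df["sample_index"]).astype(int))

    traces: list[MEPTrace] = []
    for (subject_id, trace_id), block in df.groupby(
            ["subject_id", "trace_id"], sort=False):
        block = block.sort_values("sample_index")
        first = block.iloc[0]
        traces.append(MEPTrace(
            subject_id=str(subject_id),
            group=_norm_enum(first["group"], GROUPS, "group"),
            site=_norm_enum(first["site"], SITES, "site"),
            muscle=_norm_enum(first["muscle"], MUSCLES, "muscle"),
            side=_norm_enum(first["side"], SIDES, "side"),
            trace_id=str(trace_id),
            sampling_rate=float(first["sampling_rate_hz"]),
            stimulus_index=int(float(first["stimulus_index"])),
            samples=block["amplitude_mv"].to_numpy(dtype=float),
        ))
    return traces


def write_mep_table(traces: Iterable[MEPTrace], path: str | Path) -> None:
    """Write traces to the canonical long-format TSV.

    Amplitudes are serialised with ``repr``-grade precision so that
    ``read_mep_table(write_mep_table(x)) == x`` bit-exactly.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    if str(path) == "":
        raise ValueError("empty output path")
    buf = io.StringIO()
    buf.write("\t".join(MEP_TSV_COLUMNS) + "\n")
    for t in traces:
        prefix = (f"{t.subject_id}\t{t.group}\t{t.site}\t{t.muscle}\t{t.side}\t"
                  f"{t.trace_id}\t{t.sampling_rate!r}\t{t.stimulus_index}")
        for i, a in enumerate(t.samples):
            buf.write(f"{prefix}\t{i}\t{float(a)!r}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Person:
    person_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affected: bool | None  # polyphasia status; None = unknown


@dataclass
class Pedigree:
    """PED-file families keyed by family id."""

    families: dict[str, dict[str, Person]] = field(default_factory=dict)

    def persons(self) -> Iterable[tuple[str, Person]]:
        for fam, members in self.families.items():
            for p in members.values():
                yield fam, p

    def trios(self) -> list[tuple[str, Person, Person, Person]]:
        """(family_id, child, father, mother) for every fully-linked trio."""
        out = []
        for fam, members in self.families.items():
            for p in members.values():
                if (p.father_id in members and p.mother_id in members):
                    out.append((fam, p, members[p.father_id], members[p.mother_id]))
        return out


_PED_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PED_AFF = {"2": True, "1": False, "0": None, "-9": None}


def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file; affected column is the polyphasia phenotype."""
    ped = Pedigree()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}: line {lineno}: expected 6 PED columns")
        fam, pid, father, mother, sex, aff = fields[:6]
        person = Person(
            person_id=pid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_PED_SEX.get(sex, "unknown"),
            affected=_PED_AFF.get(aff),
        )
        ped.families.setdefault(fam, {})[pid] = person
    _check_acyclic(ped)
    return ped


def _check_acyclic(ped: Pedigree) -> None:
    for fam, members in ped.families.items():
        for start in members:
            seen = set()
            stack = [start]
            while stack:
                pid = stack.pop()
                if pid in seen:
                    raise FormatError(f"cyclic parentage in family {fam} at {pid}")
                seen.add(pid)
                p = members.get(pid)
                if p is None:
                    continue
                stack.extend(x for x in (p.father_id, p.mother_id) if x and x == start)
        # full ancestor-of-self check
        for start in members:
            frontier = {start}
            ancestors: set[str] = set()
            while frontier:
                nxt = set()
                for pid in frontier:
                    p = members.get(pid)
                    if p is None:
                        continue
                    for parent in (p.father_id, p.mother_id):
                        if parent and parent not in ancestors:
                            nxt.add(parent)
                            ancestors.add(parent)
                if start in ancestors:
                    raise FormatError(f"cyclic parentage in family {fam} at {start}")
                frontier = nxt


# ---------------------------------------------------------------------------
# Variants / genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic variant with its functional annotation and reference MAFs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str = ""
    impact: str = "MODIFIER"
    region: str = "other"
    maf_1000g: float | None = None
    maf_esp: float | None = None
    maf_exac: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be ≥ 1 (VCF is 1-based)")
        impact = _IMPACT_SYNONYMS.get(self.impact.upper(), self.impact.upper())
        object.__setattr__(self, "impact", impact)
        if impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        for name in ("maf_1000g", "maf_esp", "maf_exac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def mafs(self) -> list[float]:
        return [v for v in (self.maf_1000g, self.maf_esp, self.maf_exac)
                if v is not None]


@dataclass
class GenotypeMatrix:
    """samples × variants alternate-allele counts with variant metadata.

    ``counts[i, j]`` is the number of alternate alleles sample *i* carries at
    variant *j*: 0, 1, 2 or NaN for a missing call. ``phenotype[i]`` is True
    for polyphasic samples (may be None when unphenotyped, e.g. controls-only
    matrices used for the exclusion filter).
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    counts: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("counts shape does not match id lists")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=bool)
            if self.phenotype.shape != (len(self.sample_ids),):
                raise ValueError("phenotype length does not match samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in idx],
            counts=self.counts[:, idx].copy(),
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            counts=self.counts[idx, :].copy(),
            phenotype=None if self.phenotype is None
            else self.phenotype[idx].copy(),
        )


def _read_annotations(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        key = f"{row['chrom']}:{int(row['pos'])}:{row['ref']}:{row['alt']}"

        def _maf(col: str) -> float | None:
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v) in ("", "NA", "."):
                return None
            return float(v)

        out[key] = dict(
            consequence=str(row["consequence"]),
            impact=str(row["impact"]),
            region=str(row["region"]),
            maf_1000g=_maf("maf_1000g"),
            maf_esp=_maf("maf_esp"),
            maf_exac=_maf("maf_exac"),
            gene=(str(row["gene"]) if "gene" in df.columns
                  and not pd.isna(row.get("gene")) else None),
        )
    return out


def read_vcf(path: str | Path,
             annotations_path: str | Path | None = None,
             phenotype: Mapping[str, bool] | None = None) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Diploid GT fields become alternate-allele counts (``0/1`` → 1, ``1/1`` → 2,
    ``./.`` → NaN). Multi-allelic sites are split into one bi-allelic record
    per alternate allele. Variants without an annotation row default to
    impact MODIFIER, region ``other``, MAFs missing.
    """
    from cyvcf2 import VCF

    ann = _read_annotations(annotations_path) if annotations_path else {}
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        gts = v.genotypes  # [[a0, a1, phased], ...]
        for ai, alt in enumerate(v.ALT, start=1):
            col = np.empty(len(sample_ids), dtype=float)
            for si, g in enumerate(gts):
                alleles = [a for a in g[:-1] if a is not None]
                if not alleles or any(a < 0 for a in alleles):
                    col[si] = np.nan
                else:
                    col[si] = sum(1 for a in alleles if a == ai)
            key = f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            meta = ann.get(key, {})
            variants.append(VariantRecord(
                chrom=str(v.CHROM), pos=int(v.POS), ref=str(v.REF), alt=str(alt),
                **meta))
            columns.append(col)
    vcf.close()
    counts = (np.column_stack(columns) if columns
              else np.empty((len(sample_ids), 0)))
    pheno = None
    if phenotype is not None:
        pheno = np.array([bool(phenotype[s]) for s in sample_ids])
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants,
                          counts=counts, phenotype=pheno)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids))
    gt_repr = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, var in enumerate(matrix.variants):
        gts = []
        for i in range(matrix.n_samples):
            c = matrix.counts[i, j]
            gts.append("./." if np.isnan(c) else gt_repr[c])
        lines.append(f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotations(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "consequence": v.consequence, "impact": v.impact, "region": v.region,
            "maf_1000g": v.maf_1000g, "maf_esp": v.maf_esp, "maf_exac": v.maf_exac,
            "gene": v.gene,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_ped(ped: Pedigree, path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {True: "2", False: "1", None: "0"}
    lines = []
    for fam, p in ped.persons():
        lines.append("\t".join([
            fam, p.person_id, p.father_id or "0", p.mother_id or "0",
            sex_code[p.sex], aff_code[p.affected]]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    # MEP scoring
    "window_pre_ms": 9.0,
    "window_post_ms": 36.0,
    "hysteresis_frac": 0.05,
    "onset_k": 3.0,
    "onset_floor_mv": 0.1,
    "polyphasia_threshold": 2,
    "min_polyphasic_fraction": 0.0,   # 0 → "any polyphasic MEP" subject rule
    # variant filtering
    "maf_max": 0.01,
    "keep_impacts": ["HIGH", "MEDIUM"],
    "keep_regions": ["coding_exonic"],
    # risk model
    "top_k": 16,
    "risk_threshold": 0.5,
    "ridge_lambda": 1e-3,
}


def load_config(path: str | Path | None) -> dict:
    """Load YAML/JSON config, apply defaults, warn on unknown keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping")
        for key, value in loaded.items():
            if key not in DEFAULT_CONFIG:
                logger.warning("config %s: unknown key %r ignored", path, key)
                continue
            cfg[key] = value
    logger.info("effective config: %s", cfg)
    return cfg
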