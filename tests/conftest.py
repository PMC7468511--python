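"""Shared fixtures: tiny hand-written genomic files and synthetic traces."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from polyphasia.formats_io import MEPTrace

TOY_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=1>
    ##contig=<ID=2>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0
    2\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t0/1\t0/0
    """)

TOY_ANNOTATIONS = textwrap.dedent("""\
    chrom\tpos\tref\talt\tconsequence\timpact\tregion\tmaf_1000g\tmaf_esp\tmaf_exac\tgene
    1\t100\tA\tG\tmissense_variant\tMEDIUM\tcoding_exonic\t0.005\tNA\t0.004\tGENE1
    """)

TOY_PED = textwrap.dedent("""\
    FAM1\tfather\t0\t0\t1\t2
    FAM1\tmother\t0\t0\t2\t1
    FAM1\tchild\tfather\tmother\t2\t2
    FAM2\tp1\t0\t0\t1\t0
    """)


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def toy_annotations(tmp_path):
    path = tmp_path / "toy.annotations.tsv"
    path.write_text(TOY_ANNOTATIONS)
    return path


@pytest.fixture
def toy_ped(tmp_path):
    path = tmp_path / "toy.ped"
    path.write_text(TOY_PED)
    return path


def make_trace(samples, sampling_rate=20_000.0, stimulus_index=None,
               **meta) -> MEPTrace:
    """Wrap a raw sample array in an MEPTrace with sane metadata."""
    samples = np.asarray(samples, dtype=float)
    if stimulus_index is None:
        stimulus_index = int(0.010 * sampling_rate)  # 10 ms pre-stimulus
    defaults = dict(subject_id="S1", group="patient", site="cortex",
                    muscle="ADM", side="right", trace_id="T1")
    defaults.update(meta)
    return MEPTrace(sampling_rate=sampling_rate, stimulus_index=stimulus_index,
                    samples=samples, **defaults)


def lobe_train(centers_ms, amps_mv, sigma_ms=0.75, sampling_rate=20_000.0,
               pre_ms=10.0, post_ms=60.0):
    """Analytic Gaussian lobe train (independent of the package generator)."""
    n_pre = int(round(pre_ms * 1e-3 * sampling_rate))
    n_post = int(round(post_ms * 1e-3 * sampling_rate))
    t = (np.arange(n_pre + n_post + 1) - n_pre) / sampling_rate * 1e3
    y = np.zeros_like(t)
    for c, a in zip(centers_ms, amps_mv):
        y += a * np.exp(-0.5 * ((t - c) / sigma_ms) ** 2)
    y[t < 0] = 0.0
    return y, n_pre
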