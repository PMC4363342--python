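import numpy as np
import pysam
import pytest
from hypothesis import settings

from aseqkit import FixtureConfig, build_fixture_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def write_bam(path, reads, chrom="chrT", length=10_000):
    """Write a coordinate-sorted indexed BAM from simple read specs.

    Each read is a dict: start (0-based), seq, and optional name, mapq,
    baseq (scalar or list), flag, cigar.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    reads = sorted(reads, key=lambda r: (r["start"], r.get("name", "")))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, spec in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = spec.get("name", f"read{i}")
            a.query_sequence = spec["seq"]
            a.reference_id = 0
            a.reference_start = spec["start"]
            a.mapping_quality = spec.get("mapq", 60)
            a.cigarstring = spec.get("cigar", f"{len(spec['seq'])}M")
            a.flag = spec.get("flag", 0)
            bq = spec.get("baseq", 30)
            if isinstance(bq, int):
                bq = [bq] * len(spec["seq"])
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in bq))
            bam.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A modest error-free paired dataset used by several test modules."""
    out = tmp_path_factory.mktemp("fixture_small")
    config = FixtureConfig(n_genes=12, snps_per_gene=(1, 2, 3), het_fraction=0.7,
                           dna_depth=30, rna_depth=30, ase_gene_fraction=0.3,
                           ase_allele_fraction=1.0, base_error_rate=0.0, seed=11)
    return config, build_fixture_dataset(config, out)


@pytest.fixture(scope="session")
def recovery_fixture(tmp_path_factory):
    """Planted mono-allelic genes (allele fraction 0.95, RNA depth 50) next to
    balanced genes, for the parameter-recovery checks."""
    out = tmp_path_factory.mktemp("fixture_recovery")
    config = FixtureConfig(n_genes=60, snps_per_gene=(1, 2, 3), het_fraction=1.0,
                           dna_depth=50, rna_depth=50, ase_gene_fraction=0.5,
                           ase_allele_fraction=0.95, base_error_rate=0.0, seed=20)
    return config, build_fixture_dataset(config, out)
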