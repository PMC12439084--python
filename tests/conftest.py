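import textwrap

import pytest

from sedapop.simulate import SimulationConfig, generate_core

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chloroplast,length=127202>
    ##contig=<ID=mitochondrion,length=43586>
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    """
)

# quality mix: three records below Q30 (29.9, 10, 5), three at/above
VCF_BODY = textwrap.dedent(
    """\
    chloroplast\t100\t.\tC\tT\t29.9\t.\t.\tAD\t6,2\t5,5
    chloroplast\t200\t.\tA\tG\t30.0\t.\t.\tAD\t6,2\t0,0
    chloroplast\t300\t.\tG\tA\t55\t.\t.\tAD\t10,0\t3,9
    chloroplast\t400\t.\tT\tTA\t60\t.\t.\tAD\t4,4\t4,4
    chloroplast\t500\t.\tC\tG,T\t60\t.\t.\tAD\t2,2,2\t2,2,2
    mitochondrion\t50\t.\tC\tT\t10\t.\t.\tAD\t6,2\t5,5
    mitochondrion\t60\t.\tG\tC\t5\t.\t.\tAD\t6,2\t5,5
    mitochondrion\t70\t.\tA\tT\t90\t.\t.\tAD\t1,3\t8,8
    """
)


@pytest.fixture(scope="session")
def fixture_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    path.write_text(VCF_HEADER + VCF_BODY)
    return str(path)


@pytest.fixture(scope="session")
def synthetic_core(tmp_path_factory):
    """One full synthetic two-core dataset, shared across tests."""
    outdir = tmp_path_factory.mktemp("core")
    cfg = SimulationConfig(seed=7, n_loci=300)
    return generate_core(cfg, str(outdir))
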