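import pytest

from glurare.pipeline import LoadedInputs, load_inputs
from glurare.simulate import study_fixture


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory) -> tuple[str, str, str]:
    """(VCF, sidecar, phenotype) paths of the fixed 83-patient study cohort."""
    out = tmp_path_factory.mktemp("fixture")
    return study_fixture(str(out))


@pytest.fixture(scope="session")
def fixture_inputs(fixture_files) -> LoadedInputs:
    return load_inputs(*fixture_files)


def write_vcf(path, sample_names, rows):
    """Write a minimal VCF; ``rows`` are (chrom, pos, ref, alt_field, gt_list)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        for chrom, pos, ref, alt, gts in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    return str(path)


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return str(path)
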