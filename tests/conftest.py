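import numpy as np
import pytest

from varloc3d.curation import VariantRecord


def make_germline(gene="G1", pos=10, cls="pathogenic", alt="V"):
    return VariantRecord(gene_symbol=gene, position=pos, ref_aa="A", alt=alt,
                         origin="germline", germline_class=cls)


def make_somatic(gene="G1", pos=10, stage="primary", samples=2, alt="V"):
    return VariantRecord(gene_symbol=gene, position=pos, ref_aa="A", alt=alt,
                         origin="somatic", tumour_stage=stage, sample_count=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
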