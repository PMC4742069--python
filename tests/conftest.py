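import numpy as np
import pandas as pd
import pytest

from riboshift import Annotation, GeneModel


@pytest.fixture
def small_annotation() -> Annotation:
    return Annotation(
        [
            GeneModel("g1", 300, 25, False),
            GeneModel("g2", 600, 25, True),
            GeneModel("g3", 150, 25, False),
        ]
    )


@pytest.fixture
def annotation_tsv(tmp_path):
    path = tmp_path / "annotation.tsv"
    path.write_text(
        "gene_id\tcds_length\tupstream_extension\tis_top\n"
        "g1\t300\t25\tfalse\n"
        "g2\t600\t25\ttrue\n"
        "g3\t150\t25\tfalse\n"
    )
    return path


def make_reads(rows):
    return pd.DataFrame(rows, columns=["gene_id", "five_prime_pos", "length"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
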