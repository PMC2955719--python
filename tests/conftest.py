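import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tandemfam.gene_models import GeneModel, Region  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_gene_files(tmp_path, parent_seq, regions, gene_id="g1",
                    strand="+", seq_id="chr"):
    """Write a one-gene FASTA + GFF3 pair and return the two paths.

    ``regions`` is a list of (kind, start, end) in 0-based half-open
    coordinates; the GFF3 written is 1-based inclusive.
    """
    fasta = tmp_path / "fam.fa"
    gff = tmp_path / "fam.gff3"
    fasta.write_text(f">{seq_id}\n{parent_seq}\n")
    type_map = {
        "promoter": ("promoter", ""),
        "utr5": ("five_prime_UTR", ""),
        "spcr": ("CDS", ";part=signal_peptide"),
        "intron": ("intron", ""),
        "mpcr": ("CDS", ";part=mature"),
        "utr3": ("three_prime_UTR", ""),
    }
    lines = ["##gff-version 3"]
    for kind, start, end in regions:
        ftype, extra = type_map[kind]
        lines.append(
            f"{seq_id}\ttest\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"Parent={gene_id}{extra}"
        )
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff


@pytest.fixture
def simple_model():
    """A compact plus-strand gene model on a 120 nt parent."""
    regions = [
        Region("promoter", 0, 20),
        Region("utr5", 20, 30),
        Region("spcr", 30, 39),
        Region("intron", 39, 59),
        Region("mpcr", 59, 107),
        Region("utr3", 107, 120),
    ]
    return GeneModel("g1", "chr", regions, "+")
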