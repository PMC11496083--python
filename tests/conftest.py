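import numpy as np
import pytest

import cd45iso as c
from cd45iso.gene_model import Exon, GeneModel


@pytest.fixture(scope="session")
def toy():
    """Toy CD45-like model (9 exons) plus its genome FASTA text."""
    return c.synthetic.make_toy_model(seed=1)


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory, toy):
    model, fasta = toy
    d = tmp_path_factory.mktemp("toy")
    (d / "genome.fa").write_text(fasta)
    (d / "annotation.gtf").write_text(c.model_to_gtf(model))
    return d


@pytest.fixture(scope="session")
def rules(toy_model):
    return c.default_ptprc_rules(toy_model)


@pytest.fixture(scope="session")
def refset(toy_model, rules):
    return c.build_reference(toy_model, rules, read_len=98, min_overlap=1)


@pytest.fixture(scope="session")
def index(refset):
    return c.build_index(refset, k=21)


@pytest.fixture(scope="session")
def simulated(toy_model, tmp_path_factory):
    """Informative-read simulation: 12 cells over 4 isoform profiles."""
    profiles = c.synthetic.make_cell_profiles(12, seed=5)
    sam, truth = c.synthetic.simulate_reads(
        toy_model, profiles, read_len=98, seed=5, reads_per_umi=2, informative_overlap=1
    )
    d = tmp_path_factory.mktemp("sim")
    path = d / "reads.sam"
    path.write_text(sam)
    records = list(c.extract_locus_reads(path, c.locus_region(toy_model)))
    return {"sam_path": path, "truth": truth, "records": records}


def model_from_seqs(seqs, gap=300, chrom="chrT", gene_id="G1"):
    """Plus-strand model with explicit exon sequences at known spacing."""
    exons = []
    pos = 100
    for i, s in enumerate(seqs):
        exons.append(Exon(f"E{i + 1}", chrom, pos + 1, pos + len(s), "+", s))
        pos += len(s) + gap
    return GeneModel(gene_id, chrom, "+", tuple(exons))


def random_seq(length, rng):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
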