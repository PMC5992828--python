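import numpy as np
import pandas as pd
import pytest

from halochic.origins import TaxonomyIndex
from halochic.pipeline import run_simulated
from halochic.simulate import SimConfig
from halochic.similarity import AlignmentHit


def make_hit(
    q="p1",
    s="p2",
    identity=90.0,
    q_start=1,
    q_end=100,
    s_start=1,
    s_end=100,
    evalue=1e-30,
    bitscore=200.0,
    aln_length=None,
):
    span = max(q_end - q_start + 1, s_end - s_start + 1)
    return AlignmentHit(
        query_id=q,
        subject_id=s,
        pct_identity=identity,
        aln_length=aln_length or span,
        mismatch=0,
        gapopen=0,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
    )


@pytest.fixture(scope="session")
def toy_taxonomy():
    rows = []
    for i in range(1, 7):
        rows.append((f"H{i}", "Archaea", "Euryarchaeota", True, "AB"[i % 2]))
        rows.append((f"A{i}", "Archaea", "Crenarchaeota", False, ""))
        phylum = ["Firmicutes", "Proteobacteria", "Actinobacteria"][i % 3]
        rows.append((f"B{i}", "Bacteria", phylum, False, ""))
    return pd.DataFrame(
        rows, columns=["genome_id", "domain", "phylum", "halo_flag", "halo_clade"]
    )


@pytest.fixture(scope="session")
def toy_taxindex(toy_taxonomy):
    # protein "xH3" lives in genome H3, etc.
    genome_of = {
        f"x{g}{suffix}": g
        for g in toy_taxonomy.genome_id
        for suffix in ("", "b", "c", "d", "e")
    }
    return TaxonomyIndex(toy_taxonomy, genome_of)


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        n_halo_genomes=8,
        n_arc_genomes=3,
        n_bact_genomes=3,
        n_background_families=12,
        n_planted_per_class={"I": 2, "II": 2, "ChiC": 2},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_sim_config):
    """One small end-to-end simulated run shared by the pipeline tests."""
    corpus, result = run_simulated(small_sim_config, mantel_permutations=99)
    return corpus, result
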