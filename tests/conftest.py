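import pandas as pd
import pytest

from phyletic import CladeLabel, GenomeRecord, PresenceMatrix
from phyletic import datasets


@pytest.fixture
def tiny_genomes():
    """4 archaea, 2 eukaryotes, 4 bacteria, 2 viruses."""
    return (
        [GenomeRecord(f"a{i}", CladeLabel.ARCHAEA) for i in range(4)]
        + [GenomeRecord(f"e{i}", CladeLabel.EUKARYOTA) for i in range(2)]
        + [GenomeRecord(f"b{i}", CladeLabel.BACTERIA) for i in range(4)]
        + [GenomeRecord(f"v{i}", CladeLabel.VIRUS) for i in range(2)]
    )


@pytest.fixture
def tiny_matrix(tiny_genomes):
    """Three families: archaeal+eukaryotic, bacterial, and ubiquitous."""
    gids = [g.genome_id for g in tiny_genomes]
    frame = pd.DataFrame(0, index=["famAE", "famB", "famAll"], columns=gids)
    frame.loc["famAE", ["a0", "a1", "a2", "a3", "e0", "e1", "v0"]] = 1
    frame.loc["famB", ["b0", "b1", "b2", "b3"]] = 1
    frame.loc["famAll"] = 1
    return PresenceMatrix(frame)


@pytest.fixture(scope="session")
def survey_records():
    """Per-protein expansion of the eleven-species essentiality survey."""
    return datasets.ribosomal_essentiality_records()


@pytest.fixture(scope="session")
def viral_matrix():
    """(matrix, genomes) reconstruction of the 24-family viral count table."""
    return datasets.viral_family_matrix()
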