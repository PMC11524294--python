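import pytest

from nucredit.models import TranscriptModel
from nucredit.simulate import SimConfig


@pytest.fixture
def tiny_config():
    """Small, fast generator configuration used across unit tests."""
    return SimConfig(
        n_transcripts=10,
        utr5_len=(30, 60),
        cds_len=(90, 150),
        utr3_len=(30, 60),
        n_sites=30,
        coverage_mean=80.0,
        n_samples=20,
        n_clusters=2,
        targets_per_cluster=3,
        ppr_per_cluster=1,
        seed=11,
    )


@pytest.fixture
def simple_transcript():
    """400 nt transcript: 5'UTR [0,100), CDS [100,400) starting ATG."""
    cds = "ATG" + "GCC" * 98 + "TAA"  # 300 nt, no internal stop
    seq = "A" * 100 + cds
    return TranscriptModel(
        id="tx1", sequence=seq, utr5=(0, 100), cds=(100, 400), utr3=(400, 400)
    )
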