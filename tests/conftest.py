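import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "smorfkit",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("smorfkit")

from smorfkit import SimulationConfig, generate_transcriptome, simulate_reads


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    config = SimulationConfig(seed=11)
    transcripts, manifest = generate_transcriptome(config)
    reads = simulate_reads(transcripts, manifest, config)
    return config, transcripts, manifest, reads


def make_psites(rel_positions, start=0, transcript_id="T", replicate="rep1",
                condition="Control", multimapping=None):
    """P-site table from ORF-relative offsets (test helper)."""
    pos = [start + p for p in rel_positions]
    return pd.DataFrame(
        {
            "transcript_id": transcript_id,
            "pos": pos,
            "length": 31,
            "multimapping": multimapping if multimapping is not None else False,
            "replicate": replicate,
            "condition": condition,
        }
    )
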