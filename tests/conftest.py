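import numpy as np
import pytest

from sahscan import ProteinRecord, SahDomain, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def myo10():
    from sahscan import reference_sah_records

    return reference_sah_records()[0]


def make_record(residues, seq_id="seq", **kw):
    return ProteinRecord(seq_id=seq_id, residues=residues, **kw)


def make_domain(subsequence, seq_id="seq", window_size=14, start=1, score=0.5):
    """A SahDomain stand-in for analytics tests (scores are placeholders)."""
    return SahDomain(
        seq_id=seq_id,
        window_size=window_size,
        start=start,
        end=start + len(subsequence) - 1,
        subsequence=subsequence,
        residue_scores=np.full(len(subsequence), score),
        domain_score=score,
        below_cutoff_fraction=0.0,
    )


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet)) for _ in range(length))
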