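import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ldfingerprint as ld

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(pid="p1.1", seq="MKVA", locus=None, scores=None):
    return ld.ProteinRecord(
        protein_id=pid,
        locus_id=locus if locus is not None else pid.rsplit(".", 1)[0],
        sequence=seq,
        scores=scores,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_proteome(rng):
    """12 scored proteins with assorted lengths and disorder contents."""
    records = []
    lengths = [5, 8, 13, 21, 34, 55, 89, 144, 233, 377, 610, 987]
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for k, L in enumerate(lengths):
        seq = "".join(rng.choice(aas, size=L))
        scores = rng.random(L)
        records.append(make_record(f"s_g{k}.1", seq, scores=scores))
    return ld.Proteome(name="small", records=records)


@pytest.fixture
def euk_prok_pair():
    euk = ld.sample_proteome(ld.eukaryote_like("euk", seed=11, n_proteins=400)).proteome()
    prok = ld.sample_proteome(ld.prokaryote_like("prok", seed=12, n_proteins=400)).proteome()
    return euk, prok


def random_fingerprint(rng, name, partition, n_tot=500):
    """Random normalized fingerprint via multinomial counts."""
    p = rng.random(partition.M * partition.N)
    p /= p.sum()
    counts = rng.multinomial(n_tot, p).reshape(partition.M, partition.N)
    return ld.Fingerprint(name=name, partition=partition, counts=counts, n_tot=n_tot)
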