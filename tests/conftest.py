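import numpy as np
import pytest

from trfm1a.core import MatureTRNA, ModificationSite, ReferenceSet, TrailerSeq
from trfm1a import simulate


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def handmade_ref():
    """Two 76-nt isodecoders sharing an identical 22-nt 3' end, a trailer,
    two miRNAs and one QC spike-in; m1A annotated at mature position 58."""
    rng = np.random.default_rng(42)
    shared_tail = _rand_seq(rng, 19) + "CCA"
    tail = "GTA" + shared_tail[3:]  # position 58 = tail[3] must be A
    tail = tail[:3] + "A" + tail[4:]
    body_a = _rand_seq(rng, 54)
    body_b = _rand_seq(rng, 54)
    while body_b[-10:] == body_a[-10:]:  # keep 5' ends distinct
        body_b = _rand_seq(rng, 54)
    trna_a = MatureTRNA("tRNA-Ala-1", "AGC", "nuclear", body_a + tail)
    trna_b = MatureTRNA("tRNA-Ala-2", "AGC", "nuclear", body_b + tail)
    trailer = TrailerSeq("tRNA-Ala-1_trailer", "tRNA-Ala-1",
                         _rand_seq(rng, 14) + "TTTT")
    mirnas = [("miR-1", _rand_seq(rng, 22)), ("miR-2", _rand_seq(rng, 21))]
    hosts = [trna_a.sequence, trna_b.sequence] + [s for _, s in mirnas]
    while True:
        spike = _rand_seq(rng, 25)
        if not simulate._shares_window(spike, hosts):
            break
    sites = [ModificationSite("tRNA-Ala-1", 58, "m1A", "TRMT6/61A"),
             ModificationSite("tRNA-Ala-2", 58, "m1A", "TRMT6/61A")]
    return ReferenceSet([trna_a, trna_b], [trailer], mirnas,
                        [("qc_spike", spike, True)], sites)


@pytest.fixture(scope="session")
def gen_ref():
    return simulate.build_reference(7, n_trna=5, n_mir=6, n_spike=2,
                                    n_control=1, n_mito=1)
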