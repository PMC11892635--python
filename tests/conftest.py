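import numpy as np
import pytest

from bicistroscan import kozak_model as km
from bicistroscan import synthetic as sim
from bicistroscan import transcript_io as tio


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    spec = sim.SimSpec.cre_like(seed=11, n_mono=150, n_bicistron=25)
    return sim.simulate_genome(spec)


@pytest.fixture(scope="session")
def trained_pwm_world():
    """(world, pwm, eval_ids): PWM trained on half of the mono start sites."""
    spec = sim.SimSpec.cre_like(seed=13, n_mono=300, n_bicistron=30)
    world = sim.simulate_genome(spec)
    by_tid = {m.transcript_id: m for m in world.models}
    sites = []
    for rec in world.truth.itertuples():
        if rec.locus_class != "monocistronic":
            continue
        rs = tio.extract_regions(by_tid[rec.transcript_id], world.genome)
        w = km.start_site_window(rs.mrna, rs.orf1.start)
        if "N" not in w:
            sites.append((rec.locus_id, w))
    train, ev = km.split_train_eval([i for i, _ in sites], seed=5)
    pwm = km.build_pwm([w for i, w in sites if i in set(train)])
    return world, pwm, ev


def make_uniform_pwm() -> km.KozakPWM:
    """All-flat PWM: every flank position has zero information."""
    probs = np.full((13, 4), 0.25)
    for i, b in zip((5, 6, 7), "ATG"):
        probs[i] = 0.0
        probs[i, "ACGT".index(b)] = 1.0
    info = np.zeros(13)
    info[[5, 6, 7]] = 2.0
    return km.KozakPWM(probs=probs, info=info, n_sites=0, pseudocount=0.0)


def make_zero_entropy_pwm(consensus: str = "GCCACATGGCGCC") -> km.KozakPWM:
    """One-hot PWM: every position carries the full 2 bits."""
    assert len(consensus) == 13 and consensus[5:8] == "ATG"
    probs = np.zeros((13, 4))
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = 1.0
    return km.KozakPWM(probs=probs, info=np.full(13, 2.0), n_sites=0,
                       pseudocount=0.0)


def random_pwm(rng: np.random.Generator, concentration: float = 1.0) -> km.KozakPWM:
    probs = rng.dirichlet([concentration] * 4, size=13)
    for i, b in zip((5, 6, 7), "ATG"):
        probs[i] = 0.0
        probs[i, "ACGT".index(b)] = 1.0
    with np.errstate(divide="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1)), 0)
    info = 2.0 + plogp.sum(axis=1)
    return km.KozakPWM(probs=probs, info=info, n_sites=0, pseudocount=0.0)


def single_exon_model(tid, chrom, strand, exon, cds_list, gene_ids=None):
    """Convenience constructor for hand-built transcript models."""
    gene_ids = gene_ids or [f"{tid}.orf{i}" for i in range(len(cds_list))]
    m = tio.TranscriptModel(
        transcript_id=tid,
        gene_ids=list(gene_ids),
        chrom=chrom,
        strand=strand,
        exons=[exon],
        orfs=[[iv] for iv in cds_list],
    )
    from bicistroscan.transcript_io import _order_and_validate_orfs

    _order_and_validate_orfs(m)
    return m
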