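import pytest

from isoseqtk.model import build_splice_chain, reciprocal_overlap
from isoseqtk.simulate import SimulationPlan, simulate


@pytest.fixture(scope="session")
def sim():
    """Default synthetic study (seed 1); shared across the whole suite."""
    return simulate(SimulationPlan(seed=1))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim):
    d = tmp_path_factory.mktemp("study")
    sim.write(d)
    return d


def match_model_to_isoform(model, isoforms):
    """Map a collapsed model back to the true isoform it represents.

    Multi-exon models match on (chrom, strand, splice chain); single-exon
    models match by reciprocal span overlap.
    """
    for iso in isoforms:
        if iso.chrom != model.chrom or iso.strand != model.strand:
            continue
        if iso.is_multi_exon or model.is_multi_exon:
            if (
                iso.is_multi_exon == model.is_multi_exon
                and build_splice_chain(iso).introns
                == build_splice_chain(model).introns
                and reciprocal_overlap(iso.span, model.span) > 0.3
            ):
                return iso
        elif reciprocal_overlap(iso.span, model.span) >= 0.5:
            return iso
    return None
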