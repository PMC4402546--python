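import pytest

from orgedit import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def desk_exp():
    """A small 10-gene synthetic silencing experiment with SAM output."""
    return simulate_experiment(SimConfig.desk_scale(seed=7), emit_sam=True)


@pytest.fixture(scope="session")
def desk_dir(desk_exp, tmp_path_factory):
    """The desk experiment written out as files (FASTA, TSVs, SAM)."""
    from orgedit import io as oio

    d = tmp_path_factory.mktemp("desk")
    oio.write_fasta(desk_exp.reference, d / "reference.fasta")
    oio.write_table(desk_exp.annotation, d / "annotation.tsv")
    oio.write_table(desk_exp.counts, d / "counts.tsv")
    oio.write_design(desk_exp.design, d / "design.tsv")
    for lib, text in desk_exp.sam_by_library.items():
        (d / f"{lib}.sam").write_text(text)
    return d
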