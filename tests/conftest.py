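import numpy as np
import pandas as pd
import pytest

from ribofitscape import (
    CallParams,
    CountTable,
    EnrichmentModel,
    Genotype,
    Mutation,
    Reference,
    count_fastq_files,
    filter_genotypes,
)
from ribofitscape.genotype_calling import parse_genotype_label
from ribofitscape.synthetic_data import (
    LandscapeConfig,
    SelectionConfig,
    simulate_landscape,
    simulate_selection_reads,
)


def build_count_table(
    subunit: str,
    entries: dict[str, dict[tuple[str, str], int]],
    replicates: list[str],
    phases: tuple[str, str] = ("pre", "post"),
) -> CountTable:
    """Hand-build a CountTable from {label: {(rep, phase): count}}."""
    cols = pd.MultiIndex.from_product([replicates, phases], names=["replicate", "phase"])
    data = pd.DataFrame(0, index=pd.Index(sorted(entries), name="genotype_label"),
                        columns=cols, dtype=np.int64)
    for lbl, cells in entries.items():
        for key, n in cells.items():
            data.loc[lbl, key] = n
    genotypes = {lbl: parse_genotype_label(lbl, subunit) for lbl in data.index}
    return CountTable(data, genotypes, subunit)


@pytest.fixture(scope="session")
def ref120() -> Reference:
    """120-nt reference with fixed bases at the positions the tests mutate:
    U at 38, C at 110 (mirroring the field's dU38 / C110U labels)."""
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=120))
    seq[37] = "T"   # U38
    seq[109] = "C"  # C110
    seq[36] = "A"   # avoid a homopolymer around the deletion position
    seq[38] = "G"
    return Reference("t1", "".join(seq))


@pytest.fixture(scope="session")
def small_landscape():
    return simulate_landscape(LandscapeConfig(seed=11, n_doubles=500))


@pytest.fixture(scope="session")
def small_pipeline(small_landscape, tmp_path_factory):
    """Error-free read simulation at moderate depth, through the full
    call -> filter -> fitness pipeline.  Shared across module tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    sim = simulate_selection_reads(
        small_landscape, SelectionConfig(seed=13, depth=100_000, error_rate=0.0), outdir
    )
    table, rejects = count_fastq_files(
        small_landscape.reference, sim.fastq_paths, CallParams(max_mutations=2)
    )
    filtered, _report = filter_genotypes(table, min_pre=10)
    results = EnrichmentModel(filtered).fit()
    return {
        "landscape": small_landscape,
        "sim": sim,
        "counts": table,
        "filtered": filtered,
        "results": results,
    }
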