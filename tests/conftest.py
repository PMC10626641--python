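import numpy as np
import pytest

from deqseq.layout import PlasmidLayout, TargetSite
from deqseq.pipeline import RunConfig, run_screen
from deqseq.simulate import SimConfig, example_layout, make_library, simulate_reads


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_layout():
    """A hand-built tiny layout: 60-nt gene, 20-nt UMI, one base-edit
    target and one excision target with a 30-nt excised stuffer."""
    rng = np.random.default_rng(5150)
    gene = random_dna(rng, 60)
    pad0, pad1, pad2, pad3, pad4 = (random_dna(rng, n) for n in (8, 6, 6, 5, 8))
    umi_ref = "N" * 20
    site = list(random_dna(rng, 20))
    site[1], site[4] = "C", "C"
    site[2] = site[3] = "A"
    bt_region = "".join(site)
    lox_site = random_dna(rng, 10)
    stuffer = random_dna(rng, 30)
    lox_region = lox_site + stuffer + lox_site
    ref = pad0 + gene + pad1 + umi_ref + pad2 + bt_region + pad3 + lox_region + pad4
    g0 = len(pad0)
    u0 = g0 + 60 + len(pad1)
    b0 = u0 + 20 + len(pad2)
    l0 = b0 + 20 + len(pad3)
    return PlasmidLayout(
        ref_id="toy", ref_seq=ref,
        gene_span=(g0, g0 + 60), umi_span=(u0, u0 + 20),
        targets=(
            TargetSite(target_id="bt", span=(b0, b0 + 20), mode="base_edit",
                       unedited_allele=bt_region, window_span=(b0 + 1, b0 + 5)),
            TargetSite(target_id="lox", span=(l0, l0 + 50), mode="excision",
                       unedited_allele=lox_region, edited_allele=lox_site),
        ),
    )


@pytest.fixture(scope="session")
def small_screen():
    """A small noisy base-edit screen processed end to end."""
    layout = example_layout(seed=7, gene_len=500)
    cfg = SimConfig(n_variants=20, reads_per_variant=60, n_controls=3, seed=7)
    gene = layout.region(layout.gene_span)
    truths = make_library(cfg, gene,
                          target_ids=tuple(t.target_id for t in layout.targets))
    reads, truths, read_truth = simulate_reads(truths, layout, cfg)
    run_cfg = RunConfig(layout=layout, min_length=600, min_cluster_size=40,
                        min_reads_per_target=40)
    result = run_screen(run_cfg, reads, log=None)
    return {"layout": layout, "cfg": cfg, "truths": truths,
            "read_truth": read_truth, "reads": reads, "result": result}
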