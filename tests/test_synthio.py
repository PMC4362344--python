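import numpy as np
import pytest

from holoest import ctld, homology, preprocess
from holoest.seqio import gc_fraction, reverse_complement
from holoest.synthio import (
    ConfigurationError,
    SampleProfile,
    SimulationConfig,
    default_config,
    mutate_peptide,
    near_duplicates,
    plant_ctld,
    random_ctld_peptide,
    simulate,
    vary_wigl,
)
from holoest.clustering import identity


def _single_sample_config(taxon_mix, gc_by_taxon, n_reads, seed=3, **kwargs):
    profile = SampleProfile(
        sample_id="only",
        taxon_mix=taxon_mix,
        gc_by_taxon=gc_by_taxon,
        rrna_fraction=kwargs.pop("rrna_fraction", 0.0),
        n_negative_controls=kwargs.pop("n_negative_controls", 0),
        **kwargs,
    )
    return SimulationConfig(per_sample=[profile], seed=seed, reads_per_sample=n_reads)


def test_degenerate_mixture_labels_every_read_host():
    cfg = _single_sample_config({"host": 1.0}, {"host": 0.5}, 100)
    sim = simulate(cfg)
    assert len(sim.samples["only"]) == 100
    assert (sim.truth_reads.taxon == "host").all()
    assert len(sim.truth_reads) == len(sim.samples["only"])


def test_fixed_seed_reproduces_byte_identical_files(tmp_path):
    cfg = default_config(seed=11, reads_per_sample=15)
    out1, out2 = tmp_path / "a", tmp_path / "b"
    simulate(cfg).write(out1)
    simulate(default_config(seed=11, reads_per_sample=15)).write(out2)
    for f1 in sorted(out1.iterdir()):
        assert (out2 / f1.name).read_bytes() == f1.read_bytes()


def test_different_seeds_differ():
    a = simulate(default_config(seed=1, reads_per_sample=10))
    b = simulate(default_config(seed=2, reads_per_sample=10))
    sa = "".join(u.seq for u in a.samples["A_elongata"])
    sb = "".join(u.seq for u in b.samples["A_elongata"])
    assert sa != sb


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigurationError):
        simulate(_single_sample_config({"host": 0.7}, {"host": 0.5}, 10))
    with pytest.raises(ConfigurationError):
        cfg = _single_sample_config({"host": 1.0}, {"host": 0.5}, 10)
        cfg.mutation_rate = 0.9
        simulate(cfg)
    with pytest.raises(ConfigurationError):
        SampleProfile(
            sample_id="x", taxon_mix={"host": 1.0}, gc_by_taxon={"host": 0.5},
            n_planted_ctld=1, n_multidomain=2,
        ).validate()


def test_truth_conditional_gc_recovered_after_polya_trim():
    """Per-taxon mean GC of cleaned (poly-A-trimmed) reads lands within
    0.02 of the configured target (law of large numbers at n=2000/taxon)."""
    cfg = _single_sample_config(
        {"host": 0.5, "symbiont": 0.5}, {"host": 0.40, "symbiont": 0.55}, 4000
    )
    sim = simulate(cfg)
    taxon_of = dict(zip(sim.truth_reads.read_id, sim.truth_reads.taxon))
    gc_by_taxon = {"host": [], "symbiont": []}
    for u in sim.samples["only"]:
        trimmed = preprocess.trim_polyA(u.seq)
        if trimmed:
            gc_by_taxon[taxon_of[u.id]].append(gc_fraction(trimmed))
    for taxon, target in (("host", 0.40), ("symbiont", 0.55)):
        assert abs(np.mean(gc_by_taxon[taxon]) - target) < 0.02


def test_pooled_gc_variance_at_least_max_component_variance():
    cfg = _single_sample_config(
        {"host": 0.5, "symbiont": 0.5}, {"host": 0.40, "symbiont": 0.55}, 2000
    )
    sim = simulate(cfg)
    taxon_of = dict(zip(sim.truth_reads.read_id, sim.truth_reads.taxon))
    values = {"host": [], "symbiont": []}
    for u in sim.samples["only"]:
        values[taxon_of[u.id]].append(u.gc)
    pooled = np.var(values["host"] + values["symbiont"])
    assert pooled >= max(np.var(values["host"]), np.var(values["symbiont"]))


def test_taxon_proportions_within_three_binomial_sd():
    mix = {"host": 0.6, "bug": 0.4}
    cfg = _single_sample_config(mix, {"host": 0.45, "bug": 0.45}, 1000)
    sim = simulate(cfg)
    counts = sim.truth_reads.taxon.value_counts()
    n = len(sim.truth_reads)
    for taxon, p in mix.items():
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts.get(taxon, 0) - n * p) <= 3 * sd


def test_some_reads_fall_below_the_length_filter():
    cfg = default_config(seed=5, reads_per_sample=300)
    sim = simulate(cfg)
    assert (sim.truth_reads.length < 200).any()


@pytest.mark.parametrize("frame", [2, -1])
def test_plant_ctld_round_trip(frame, rng):
    template = random_ctld_peptide(rng)
    nt = plant_ctld(template, frame)
    assert template in homology.six_frame_translate(nt)[frame]


def test_plant_ctld_rejects_bad_inputs(rng):
    with pytest.raises(ValueError):
        plant_ctld("MKVLAEQT", 1)  # no grammar match
    with pytest.raises(ValueError):
        plant_ctld(random_ctld_peptide(rng), 4)


def test_random_templates_recovered_by_scan_in_all_frames(rng):
    """Ten random grammar-conformant templates planted in random frames are
    all found by the scanner with correct in-frame coordinates."""
    for _ in range(10):
        template = random_ctld_peptide(rng)
        frame = int(rng.choice([1, 2, 3, -1, -2, -3]))
        nt = plant_ctld(template, frame)
        pep = homology.six_frame_translate(nt)[frame]
        offset = pep.find(template)
        doms = ctld.scan(pep)
        (want,) = ctld.scan(template)
        assert any(
            d.start == offset + want.start and d.end == offset + want.end
            for d in doms
        )


def test_near_duplicates_stay_above_dedupe_threshold(rng):
    base = random_ctld_peptide(rng)
    copies = near_duplicates(rng, base, 5)
    pool = [base] + copies
    for i, a in enumerate(pool):
        for b in pool[i + 1 :]:
            assert identity(a, b) >= 0.97


def test_mutate_peptide_preserves_architecture(rng):
    base = random_ctld_peptide(rng)
    (want,) = ctld.scan(base)
    mutated = mutate_peptide(rng, base, 0.14)
    (got,) = ctld.scan(mutated)
    assert got.cys_positions == want.cys_positions
    assert got.sugar_motif == want.sugar_motif
    assert identity(base, mutated) < 1.0


def test_vary_wigl_keeps_grammar_validity(rng):
    base = random_ctld_peptide(rng)
    varied = vary_wigl(rng, base)
    (dom,) = ctld.scan(varied)
    assert ctld.CTLDGrammar().wigl_matches(dom.wigl)


def test_default_config_mirrors_study_design():
    cfg = default_config()
    cfg.validate()
    planted = {p.sample_id: p.n_planted_ctld for p in cfg.per_sample}
    assert planted["A_scolymantha"] == 0  # the non-photosymbiotic sample
    ss = next(p for p in cfg.per_sample if p.sample_id == "S_streptacantha")
    assert ss.n_planted_ctld + ss.n_redundant_copies == 28
    assert ss.n_planted_ctld == 8
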