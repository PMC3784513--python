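"""Strand orientation, splice-position profiles and junction conservation."""

import numpy as np
import pandas as pd
import pytest

import mutmotif as mm
from mutmotif.transcription import Junction


def _catalog(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample"])
    return mm.from_dataframe(df)


@pytest.fixture(scope="module")
def plus_gene():
    # exons 11-40 and 101-130, intron 41-100 on the + strand
    return mm.GeneModel("gA", "c", "+", [(11, 40), (101, 130)])


@pytest.fixture(scope="module")
def minus_gene():
    return mm.GeneModel("gB", "c", "-", [(211, 240), (301, 330)])


class TestGeneModel:
    def test_introns_and_junction_count(self, plus_gene):
        assert plus_gene.introns == [(41, 100)]
        kinds = sorted(j.kind for j in plus_gene.junctions())
        assert kinds == ["acceptor", "donor"]

    def test_single_exon_gene_has_no_junctions(self):
        g = mm.GeneModel("g", "c", "+", [(1, 50)])
        assert g.junctions() == []

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            mm.GeneModel("g", "c", "+", [(1, 50), (40, 80)])

    def test_reader_round_trip(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gA\tc\t+\t11,101\t40,130\ngB\tc\t-\t211,301\t240,330\n")
        genes = mm.read_gene_models(p)
        assert [g.gene_id for g in genes] == ["gA", "gB"]
        assert genes[0].exons == [(11, 40), (101, 130)]

    def test_bed12_reader(self, tmp_path):
        p = tmp_path / "genes.bed"
        # chromStart 10, two blocks of 30 starting at 0 and 90 -> exons 11-40, 101-130
        p.write_text("c\t10\t130\tgA\t0\t+\t10\t130\t0\t2\t30,30\t0,90\n")
        (gene,) = mm.read_gene_models(p)
        assert gene.exons == [(11, 40), (101, 130)]
        assert gene.strand == "+"


@pytest.fixture(scope="module")
def index(plus_gene, minus_gene):
    overlap_a = mm.GeneModel("oA", "c", "+", [(401, 500)])
    overlap_b = mm.GeneModel("oB", "c", "-", [(451, 550)])
    return mm.GeneIndex([plus_gene, minus_gene, overlap_a, overlap_b])


class TestOrientation:

    def test_g_in_plus_gene_is_non_transcribed(self, index):
        assert mm.orient_mutation("c", 20, "G", index) == "NT"

    def test_c_in_plus_gene_is_template(self, index):
        assert mm.orient_mutation("c", 20, "C", index) == "T"

    def test_minus_gene_flips(self, index):
        assert mm.orient_mutation("c", 220, "C", index) == "NT"
        assert mm.orient_mutation("c", 220, "G", index) == "T"

    def test_intergenic_and_ambiguous(self, index):
        assert mm.orient_mutation("c", 5, "G", index) == "intergenic"
        assert mm.orient_mutation("c", 460, "G", index) == "ambiguous"

    def test_at_reference_rejected(self, index):
        with pytest.raises(ValueError, match="G/C"):
            mm.orient_mutation("c", 20, "A", index)


@pytest.fixture(scope="module")
def setting():
    cfg = mm.SyntheticConfig(
        genome_length=100_000, n_genes=10, n_samples=6, mu=1e-3,
        mappable_fraction=1.0,
    )
    sim = mm.simulate_catalog(cfg, 31)
    ds = mm.deduplicate(mm.from_dataframe(sim["records"]))
    return sim, ds


class TestStrandRatio:

    def test_counts_partition_records(self, setting):
        sim, ds = setting
        index = mm.GeneIndex(sim["genes"])
        tallies = {"NT": 0, "T": 0, "ambiguous": 0, "intergenic": 0}
        n_gc = 0
        for row in ds.records.itertuples(index=False):
            if row.ref in "GC":
                n_gc += 1
                tallies[mm.orient_mutation(row.chrom, row.pos, row.ref, index)] += 1
        assert sum(tallies.values()) == n_gc == len(ds)

    def test_mirroring_gene_strands_swaps_nt_and_t(self, setting):
        sim, ds = setting
        index = mm.GeneIndex(sim["genes"])
        flipped = mm.GeneIndex(
            [
                mm.GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                             g.exons)
                for g in sim["genes"]
            ]
        )
        a = mm.strand_ratio_per_motif(ds, index, sim["genome"])
        b = mm.strand_ratio_per_motif(ds, flipped, sim["genome"])
        assert (a["NT"] == b["T"]).all() and (a["T"] == b["NT"]).all()

    def test_unbiased_process_is_roughly_symmetric(self, setting):
        sim, ds = setting
        index = mm.GeneIndex(sim["genes"])
        sr = mm.strand_ratio_per_motif(ds, index, sim["genome"])
        nt, t = sr["NT"].sum(), sr["T"].sum()
        assert nt + t > 50
        ratio = nt / t
        se = np.sqrt(1 / nt + 1 / t)  # log-scale Poisson standard error
        assert abs(np.log(ratio)) < 3 * se


class TestSpliceProfile:
    def test_donor_positions_plus_strand(self, plus_gene):
        index = mm.GeneIndex([plus_gene])
        # intron 41-100: first intronic base 41 (+1), last exonic 40 (-1)
        ds = _catalog(
            [("c", 41, "G", "T", "S1"), ("c", 40, "G", "T", "S1"),
             ("c", 42, "G", "T", "S1")]
        )
        # synthetic positions: use a catalog without genome checks
        prof = mm.splice_position_profile(ds, index)
        assert prof["donor"][1] == 1
        assert prof["donor"][-1] == 1
        assert prof["donor"][2] == 1

    def test_acceptor_positions_minus_strand(self, minus_gene):
        index = mm.GeneIndex([minus_gene])
        # intron 241-300 on minus strand: acceptor side at 241 (-1), 242 (-2)
        ds = _catalog([("c", 241, "C", "T", "S1"), ("c", 242, "C", "A", "S1"),
                       ("c", 240, "G", "A", "S1")])
        prof = mm.splice_position_profile(ds, index)
        assert prof["acceptor"][-1] == 1
        assert prof["acceptor"][-2] == 1
        assert prof["acceptor"][1] == 1  # first exonic base downstream

    def test_no_mutations_gives_zero_profile(self, plus_gene):
        index = mm.GeneIndex([plus_gene])
        prof = mm.splice_position_profile(_catalog([]), index)
        assert prof["donor"].sum() == 0 and prof["acceptor"].sum() == 0
        assert 0 not in prof["donor"].index

    def test_profile_total_bounded_by_records(self, plus_gene, minus_gene):
        index = mm.GeneIndex([plus_gene, minus_gene])
        ds = _catalog([("c", p, "G", "T", "S1") for p in range(30, 60)])
        prof = mm.splice_position_profile(ds, index)
        assert prof["donor"].sum() + prof["acceptor"].sum() <= len(ds) + prof["n_ties"]


@pytest.fixture(scope="module")
def sim():
    cfg = mm.SyntheticConfig(genome_length=100_000, n_genes=12, n_samples=1)
    return mm.simulate_catalog(cfg, 17)


class TestJunctionConservation:

    def test_canonical_dinucleotides_fully_conserved(self, sim):
        index = mm.GeneIndex(sim["genes"])
        cons = mm.junction_conservation(sim["genome"], index, window=25)
        donor = cons["donor"]["frequencies"]
        acceptor = cons["acceptor"]["frequencies"]
        assert donor.loc[1, "G"] == 1.0 and donor.loc[2, "T"] == 1.0
        assert acceptor.loc[-2, "A"] == 1.0 and acceptor.loc[-1, "G"] == 1.0

    def test_interior_positions_near_background(self, sim):
        index = mm.GeneIndex(sim["genes"])
        cons = mm.junction_conservation(sim["genome"], index, window=25)
        interior = cons["donor"]["conservation"].loc[10:20]
        assert (interior < 0.6).all()  # random interiors near base composition

    def test_single_junction_is_degenerate(self):
        genome = mm.Genome({"c": "A" * 10 + "GT" + "A" * 16 + "AG" + "C" * 10})
        gene = mm.GeneModel("g", "c", "+", [(1, 10), (31, 40)])
        cons = mm.junction_conservation(genome, mm.GeneIndex([gene]), window=5)
        freq = cons["donor"]["frequencies"]
        assert set(np.unique(freq.to_numpy())) <= {0.0, 1.0}
        assert cons["donor"]["n_junctions"] == 1


def test_offset_conventions_are_involutive():
    """Signed positions skip zero and are symmetric under strand flips."""
    j_plus = Junction("donor", "c", "+", 41, 100)
    j_minus = Junction("donor", "c", "-", 41, 100)
    offs_plus = [j_plus.offset(p) for p in range(30, 111)]
    offs_minus = [j_minus.offset(p) for p in range(30, 111)]
    assert 0 not in offs_plus and 0 not in offs_minus
    # minus-strand donor mirrors the plus-strand donor of the same intron
    assert sorted(o for o in offs_plus if abs(o) <= 5) == sorted(
        o for o in offs_minus if abs(o) <= 5
    )
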