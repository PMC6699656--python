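"""Orthology-table parsing, family classification and ortholog scores."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panoric import (
    OrthologFamily,
    PanGenome,
    classify_families,
    ortholog_scores,
    pangenome_summary,
    read_proteinortho,
    reduce_one_per_genus,
    soft_core_threshold,
    write_proteinortho,
)


def _write(tmp_path, text):
    path = tmp_path / "families.tsv"
    path.write_text(textwrap.dedent(text))
    return path


class TestReadProteinortho:
    def test_paralog_row(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            # Species\tGenes\tAlg.-Conn.\tA\tB
            2\t3\t0.5\ta1,a2\tb1
            """,
        )
        pan = read_proteinortho(path)
        fam = pan.families[0]
        assert fam.n_species == 2 and fam.n_genes == 3
        assert fam.members["A"] == ["a1", "a2"] and fam.has_paralogs
        assert fam.connectivity == 0.5

    def test_strain_specific_row(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            # Species\tGenes\tAlg.-Conn.\tA\tB\tC
            1\t1\t1\t*\tb1\t*
            """,
        )
        pan = read_proteinortho(path)
        assert pan.families[0].n_species == 1
        assert list(pan.families[0].members) == ["B"]

    def test_bad_header_rejected(self, tmp_path):
        path = _write(tmp_path, "Species\tGenes\tA\n1\t1\ta1\n")
        with pytest.raises(ValueError, match="Proteinortho"):
            read_proteinortho(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            # Species\tGenes\tAlg.-Conn.\tA\tB
            1\t1\t1\ta1\t*
            1\t1\t1\ta1\t*
            """,
        )
        with pytest.raises(ValueError, match="a1"):
            read_proteinortho(path)

    def test_count_mismatch_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            # Species\tGenes\tAlg.-Conn.\tA\tB
            2\t2\t1\ta1\t*
            """,
        )
        with pytest.raises(ValueError, match="declares"):
            read_proteinortho(path)

    def test_round_trip(self, tmp_path, small_pangenome):
        _, _, pan, _ = small_pangenome
        path = tmp_path / "rt.tsv"
        write_proteinortho(path, pan)
        back = read_proteinortho(path)
        assert back.strains == pan.strains
        assert len(back.families) == len(pan.families)
        for a, b in zip(pan.families, back.families):
            assert a.members == b.members
            assert a.connectivity == b.connectivity


class TestClassification:
    @pytest.mark.parametrize(
        "n_strains,fraction,expected",
        [(109, 0.95, 104), (20, 0.95, 19), (10, 1.0, 10), (109, 0.5, 55)],
    )
    def test_soft_core_threshold_ceiling_rule(self, n_strains, fraction, expected):
        assert soft_core_threshold(n_strains, fraction) == expected

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            soft_core_threshold(10, 0.0)
        with pytest.raises(ValueError):
            soft_core_threshold(10, 1.5)

    def test_labels_and_flags(self, toy_pan):
        table, thr = classify_families(toy_pan, soft_core_fraction=0.75)
        assert thr == 3
        by_id = table.set_index("family_id")
        assert by_id.loc["fam0", "label"] == "core"
        assert by_id.loc["fam1", "label"] == "soft_core"
        assert by_id.loc["fam2", "label"] == "accessory"
        assert bool(by_id.loc["fam3", "has_paralogs"])
        assert not bool(by_id.loc["fam0", "has_paralogs"])

    def test_core_with_paralog_excluded_from_no_paralog_count(self):
        pan = PanGenome(
            strains=["A", "B"],
            families=[OrthologFamily("f", {"A": ["a1", "a2"], "B": ["b1"]}, 1.0)],
        )
        table, _ = classify_families(pan)
        summary = pangenome_summary(table)
        assert summary.loc[0, "core_incl_paralogs"] == 1
        assert summary.loc[0, "core_no_paralogs"] == 0

    def test_count_ordering_core_soft_total(self, small_pangenome):
        _, _, pan, _ = small_pangenome
        table, _ = classify_families(pan)
        s = pangenome_summary(table)
        assert (
            s.loc[0, "core_incl_paralogs"]
            <= s.loc[0, "soft_core_incl_paralogs"]
            <= s.loc[0, "n_families"]
        )

    def test_connectivity_filter_monotone(self, small_pangenome):
        _, _, pan, _ = small_pangenome
        counts = []
        for t in (0.0, 0.5, 0.9, 0.99):
            table, _ = classify_families(pan, connectivity_min=t)
            counts.append(
                int((table["is_core"] & ~table["has_paralogs"] & table["high_connectivity"]).sum())
            )
        assert counts == sorted(counts, reverse=True)

    def test_recovers_generator_occupancy(self, small_pangenome):
        _, _, pan, truth = small_pangenome
        for fam in pan.families:
            assert fam.n_species == truth.family_occupancy[fam.family_id]

    @given(
        st.lists(
            st.lists(st.integers(0, 2), min_size=3, max_size=3),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_gene_conservation_property(self, rows):
        """Sum of per-family member counts equals the total genes in the table."""
        strains = ["A", "B", "C"]
        counter = iter(range(10_000))
        families = []
        for r, row in enumerate(rows):
            members = {
                s: [f"g{next(counter)}" for _ in range(k)] for s, k in zip(strains, row) if k
            }
            if members:
                families.append(OrthologFamily(f"f{r}", members, 1.0))
        if not families:
            return
        pan = PanGenome(strains=strains, families=families)
        assert sum(f.n_genes for f in pan.families) == len(pan.gene_index)


class TestOrthologScores:
    def test_focal_strain_excluded(self, toy_pan):
        scores = ortholog_scores(toy_pan, "A").set_index("gene_id")["ortholog_score"]
        assert scores["a0"] == 3  # family of all 4 strains -> 3 others
        assert scores["a1"] == 2  # focal + 2 others
        assert scores["a2"] == 0  # strain-specific

    def test_max_score_in_all_core_pangenome(self):
        strains = [f"S{i}" for i in range(5)]
        fams = [
            OrthologFamily(f"f{j}", {s: [f"{s}_g{j}"] for s in strains}, 1.0) for j in range(3)
        ]
        pan = PanGenome(strains=strains, families=fams)
        for s in strains:
            assert set(ortholog_scores(pan, s)["ortholog_score"]) == {len(strains) - 1}

    def test_unknown_strain_rejected(self, toy_pan):
        with pytest.raises(ValueError, match="unknown strain"):
            ortholog_scores(toy_pan, "Z")

    def test_unannotated_gene_scored_zero_and_flagged(self, toy_pan):
        table = ortholog_scores(toy_pan, "A", ["a0", "ghost"]).set_index("gene_id")
        assert table.loc["ghost", "ortholog_score"] == 0
        assert not bool(table.loc["ghost", "in_table"])
        assert bool(table.loc["a0", "in_table"])


class TestReduceOnePerGenus:
    def test_distinct_genera_identity(self, toy_pan):
        genus = {s: s for s in toy_pan.strains}
        red = reduce_one_per_genus(toy_pan, genus, seed=1)
        assert red.strains == toy_pan.strains
        assert len(red.families) == len(toy_pan.families)

    def test_same_genus_collapses_family(self):
        pan = PanGenome(
            strains=["A", "B"],
            families=[OrthologFamily("f", {"A": ["a1"], "B": ["b1"]}, 1.0)],
        )
        red = reduce_one_per_genus(pan, {"A": "g", "B": "g"}, seed=0)
        assert len(red.strains) == 1
        assert red.families[0].n_species == 1

    def test_three_genera_two_strains_each(self):
        strains = [f"{g}{i}" for g in "XYZ" for i in (1, 2)]
        fams = [OrthologFamily("f0", {s: [f"{s}_g"] for s in strains}, 1.0)]
        pan = PanGenome(strains=strains, families=fams)
        genus = {s: s[0] for s in strains}
        red = reduce_one_per_genus(pan, genus, seed=3)
        assert len(red.strains) == 3
        assert sorted({genus[s] for s in red.strains}) == ["X", "Y", "Z"]

    def test_empty_families_dropped(self):
        pan = PanGenome(
            strains=["A", "B"],
            families=[
                OrthologFamily("kept", {"A": ["a1"], "B": ["b1"]}, 1.0),
                OrthologFamily("dropme", {"B": ["b2"]}, 1.0),
            ],
        )
        # force keeping A by making B's genus collide with A's
        red = reduce_one_per_genus(pan, {"A": "g", "B": "g"}, seed=4)
        if red.strains == ["A"]:
            assert [f.family_id for f in red.families] == ["kept"]
        else:
            assert {f.family_id for f in red.families} == {"kept", "dropme"}

    def test_incomplete_genus_map_rejected(self, toy_pan):
        with pytest.raises(ValueError, match="cover"):
            reduce_one_per_genus(toy_pan, {"A": "g"}, seed=0)
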