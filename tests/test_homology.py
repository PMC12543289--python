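import numpy as np
import pandas as pd
import pytest

from ripscan import (
    bin_protein_hits,
    bin_repeat_hits,
    dedupe_hits,
    pangenome_categories,
    read_alignment_table,
    reciprocal_best_hits,
    select_focal_orthogroups,
    synteny_scores,
)
from ripscan.homology import ALIGNMENT_COLUMNS


def records(rows):
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def hit(q, s, pident=90.0, length=500, mismatch=5, gapopen=0, qstart=1,
        qend=500, sstart=1, send=500, evalue=1e-50, bitscore=900.0):
    return (q, s, pident, length, mismatch, gapopen, qstart, qend, sstart,
            send, evalue, bitscore)


class TestDedupe:
    def test_self_hit_removed(self):
        df = records([hit("A", "A"), hit("A", "B")])
        out = dedupe_hits(df)
        assert list(out["sseqid"]) == ["B"]

    def test_identically_scored_duplicates_collapse(self):
        df = records([hit("A", "B", sstart=1), hit("A", "B", sstart=7)])
        # same pident/length/mismatch/gapopen/qstart: keep first only
        out = dedupe_hits(df)
        assert len(out) == 1 and out.loc[0, "sstart"] == 1

    def test_reciprocal_hits_are_kept(self):
        df = records([hit("A", "B"), hit("B", "A")])
        assert len(dedupe_hits(df)) == 2

    def test_same_pair_different_region_kept(self):
        df = records([hit("A", "A", qstart=1, sstart=600, qend=500, send=1100)])
        assert len(dedupe_hits(df)) == 1  # self id but shifted coords


class TestRepeatBins:
    def test_cumulative_length_bins(self):
        prof = bin_repeat_hits(records([hit("A", "B", pident=97, length=6000)]))
        col = prof.counts[">95"]
        assert col[">100"] == col[">1000"] == col[">5000"] == 1
        assert col[">10000"] == 0

    def test_single_bin_low_identity(self):
        prof = bin_repeat_hits(records([hit("A", "B", pident=85, length=150)]))
        assert prof.counts.loc[">100", "80-95"] == 1
        assert prof.counts.to_numpy().sum() == 1

    def test_boundaries_are_strict(self):
        prof = bin_repeat_hits(records([hit("A", "B", pident=95, length=100)]))
        assert prof.counts.to_numpy().sum() == 0  # length must exceed 100
        prof = bin_repeat_hits(records([hit("A", "B", pident=95, length=101)]))
        assert prof.counts.loc[">100", "80-95"] == 1  # pident 95 is not >95

    def test_below_80_ignored(self):
        prof = bin_repeat_hits(records([hit("A", "B", pident=70, length=5000)]))
        assert prof.counts.to_numpy().sum() == 0

    def test_matches_bruteforce_reclassification(self):
        """Binning equals an independent per-record oracle on random hits."""
        rng = np.random.default_rng(42)
        rows = [
            hit(
                f"q{i}", f"s{i}",
                pident=float(rng.uniform(75, 100)),
                length=int(rng.integers(50, 20_000)),
            )
            for i in range(200)
        ]
        df = records(rows)
        prof = bin_repeat_hits(df)
        oracle = {(f">{t}", ib): 0 for t in (100, 1000, 5000, 10000)
                  for ib in ("80-95", ">95")}
        for r in rows:
            pident, length = r[2], r[3]
            if pident < 80:
                continue
            ib = ">95" if pident > 95 else "80-95"
            for t in (100, 1000, 5000, 10000):
                if length > t:
                    oracle[(f">{t}", ib)] += 1
        for (lb, ib), n in oracle.items():
            assert prof.counts.loc[lb, ib] == n
        assert prof.n_1kb == oracle[(">1000", ">95")]

    def test_exclusive_mode_partitions(self):
        rng = np.random.default_rng(43)
        rows = [
            hit(f"q{i}", f"s{i}", pident=float(rng.uniform(80, 100)),
                length=int(rng.integers(101, 20_000)))
            for i in range(100)
        ]
        prof = bin_repeat_hits(records(rows), cumulative=False)
        assert prof.counts.to_numpy().sum() == 100


class TestProteinBins:
    @pytest.mark.parametrize(
        "length,expected",
        [(50, "<=50"), (51, "50-100"), (100, "50-100"), (500, "100-500"),
         (600, ">500")],
    )
    def test_bin_boundaries(self, length, expected):
        out = bin_protein_hits(records([hit("A", "B", length=length)]))
        assert out.loc[0, "length_bin"] == expected


class TestReciprocalBestHits:
    def test_mutual_top_hits_pair(self):
        ab = records([hit("a", "b", bitscore=900), hit("a", "c", bitscore=100)])
        ba = records([hit("b", "a", bitscore=900)])
        assert reciprocal_best_hits(ab, ba) == {("a", "b")}

    def test_non_mutual_best_is_excluded(self):
        ab = records([hit("a", "b", bitscore=900)])
        ba = records([hit("b", "c", bitscore=900), hit("b", "a", bitscore=100)])
        assert reciprocal_best_hits(ab, ba) == set()

    def test_tie_broken_by_input_order_and_logged(self, caplog):
        ab = records([
            hit("a", "b1", bitscore=500, evalue=1e-40),
            hit("a", "b2", bitscore=500, evalue=1e-40),
        ])
        ba = records([hit("b1", "a", bitscore=500)])
        with caplog.at_level("WARNING"):
            pairs = reciprocal_best_hits(ab, ba)
        assert pairs == {("a", "b1")}
        assert "tie" in caplog.text

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        ab = records([
            hit(f"a{i}", f"b{rng.integers(5)}", bitscore=float(rng.integers(100, 999)))
            for i in range(5) for _ in range(3)
        ])
        ba = records([
            hit(f"b{i}", f"a{rng.integers(5)}", bitscore=float(rng.integers(100, 999)))
            for i in range(5) for _ in range(3)
        ])
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert fwd == {(a, b) for b, a in rev}


class TestPangenome:
    def _presence(self, fractions, n_species=100):
        data = {}
        for og, frac in fractions.items():
            v = np.zeros(n_species, dtype=int)
            v[: int(round(frac * n_species))] = 1
            data[og] = v
        return pd.DataFrame(data, index=[f"sp{i}" for i in range(n_species)])

    def test_threshold_bands(self):
        cats = pangenome_categories(
            self._presence({"og_core": 0.928, "og_soft": 0.85, "og_shell": 0.6,
                            "og_var": 0.3, "og_single": 0.01})
        )
        assert cats["og_core"] == "core"
        assert cats["og_soft"] == "softcore"
        assert cats["og_shell"] == "shell"
        assert cats["og_var"] == "variable"
        assert cats["og_single"] == "singleton"

    def test_exactly_half_is_variable(self):
        cats = pangenome_categories(self._presence({"og": 0.5}))
        assert cats["og"] == "variable"

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(11)
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(60, 200)),
            columns=[f"og{i}" for i in range(200)],
        )
        presence.iloc[0] = 1  # no all-absent orthogroup
        cats = pangenome_categories(presence)
        assert len(cats) == 200
        assert cats.isin(
            ["core", "softcore", "shell", "variable", "singleton"]
        ).all()

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            pangenome_categories(pd.DataFrame())


class TestFocalSelection:
    def _membership(self, rows):
        return pd.DataFrame(rows, columns=["species", "orthogroup", "gene_id"])

    def test_conjunctive_filters(self):
        rows = []
        classes = {}
        # og_good: in 20/100 species, single copy, 10 classes
        for i in range(100):
            classes[f"sp{i}"] = f"cls{i % 10}"
        for i in range(20):
            rows.append((f"sp{i}", "og_good", f"g{i}"))
        # og_rare: 4% presence
        for i in range(4):
            rows.append((f"sp{i}", "og_rare", f"r{i}"))
        # og_multi: 20 species but multi-copy in 30% of them
        for i in range(20):
            rows.append((f"sp{i}", "og_multi", f"m{i}"))
            if i < 6:
                rows.append((f"sp{i}", "og_multi", f"m{i}b"))
        # og_narrow: 20 species but only 2 classes
        for i in range(20):
            rows.append((f"sp{2 * (i % 2)}", "og_narrow", f"n{i}"))
        focal = select_focal_orthogroups(
            self._membership(rows), classes, n_species=100
        )
        assert focal == {"og_good"}


class TestSynteny:
    def _orders(self, species_orders):
        rows = []
        for sp, scaffolds in species_orders.items():
            for scaf, ogs in scaffolds.items():
                for rank, og in enumerate(ogs):
                    rows.append((sp, scaf, rank, og))
        return pd.DataFrame(
            rows, columns=["species", "scaffold", "rank", "orthogroup"]
        )

    def test_identical_genomes_give_mean_one(self):
        order = {"c1": [f"og{i}" for i in range(21)]}
        df = self._orders({"sp1": order, "sp2": order})
        out = synteny_scores(df, ["og10"]).set_index("orthogroup")
        assert out.loc["og10", "mean_synteny"] == pytest.approx(1.0)
        assert out.loc["og10", "n_species"] == 2

    def test_scrambled_neighborhood_gives_half(self):
        df = self._orders(
            {
                "sp1": {"c1": ["og1", "og2", "focal", "og3", "og4"]},
                "sp2": {"c1": ["uq1", "uq2", "focal", "uq3", "uq4"]},
            }
        )
        out = synteny_scores(df, ["focal"]).set_index("orthogroup")
        # every neighbor orthogroup occurs in exactly 1 of the 2 carriers
        assert out.loc["focal", "mean_synteny"] == pytest.approx(0.5)

    def test_window_truncated_at_scaffold_end(self):
        order = ["og0", "og1", "og2", "focal"] + [f"og{i}" for i in range(3, 15)]
        df = self._orders({"sp1": {"c1": order}})
        out = synteny_scores(df, ["focal"], window=10).set_index("orthogroup")
        # 3 upstream (truncated) + 10 downstream neighbors
        assert out.loc["focal", "n_neighbors"] == 13

    def test_windows_do_not_cross_scaffolds(self):
        df = self._orders(
            {"sp1": {"c1": ["og1", "focal"], "c2": ["far1", "far2"]}}
        )
        out = synteny_scores(df, ["focal"]).set_index("orthogroup")
        assert out.loc["focal", "n_neighbors"] == 1

    def test_multicopy_focal_windows_union(self):
        df = self._orders(
            {"sp1": {"c1": ["og1", "focal", "og2", "focal", "og3"]}}
        )
        out = synteny_scores(df, ["focal"], window=1).set_index("orthogroup")
        # windows around both copies: og1, og2 and og2, og3
        assert out.loc["focal", "n_neighbors"] == 3

    def test_absent_focal_is_error(self):
        df = self._orders({"sp1": {"c1": ["og1", "og2"]}})
        with pytest.raises(ValueError):
            synteny_scores(df, ["ghost"])


def test_read_alignment_table_roundtrip(tmp_path):
    df = records([hit("A", "B"), hit("B", "C", pident=99.5)])
    path = tmp_path / "hits.tsv"
    df.to_csv(path, sep="\t", header=False, index=False)
    back = read_alignment_table(path)
    assert list(back["qseqid"]) == ["A", "B"]
    assert back.loc[1, "pident"] == 99.5
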