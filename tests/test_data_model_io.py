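import json

import pandas as pd
import pytest

from scatdiet import (
    DietProfile,
    FilterConfig,
    OverlapResult,
    RarefactionCurve,
    ReadCountTable,
    ScatStatus,
    TaxonRecord,
    Taxonomy,
    read_read_count_table,
    read_taxonomy_table,
    write_results,
)
from scatdiet.data_model_io import (
    IncidenceFrequencies,
    read_results_json,
    write_read_count_table,
    write_taxonomy_table,
)
from conftest import make_scat

TAXONOMY_CSV = """taxon_id,class_name,order_name,family_name,genus_name,species_name,candidate_defecator
red_fox,Mammalia,Carnivora,Canidae,Vulpes,Vulpes vulpes,true
coyote,Mammalia,Carnivora,Canidae,Canis,Canis latrans,true
vole,Mammalia,Rodentia,Cricetidae,Myodes,Myodes californicus,false
"""


class TestTaxonRecord:
    def test_carnivore_flag_requires_carnivora(self):
        with pytest.raises(ValueError, match="Carnivora"):
            TaxonRecord("cat", "Mammalia", "Rodentia", "F", "G", "S", True)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class_name"):
            TaxonRecord("x", "", "Rodentia", "F", "G", "S", False)

    def test_rank_rollup_for_genus_level_item(self):
        rec = TaxonRecord("chipmunk", "Mammalia", "Rodentia", "Sciuridae", "Tamias", "", False)
        assert rec.rank_label("species") == "Tamias"  # rolls up to genus
        assert rec.rank_label("family") == "Sciuridae"

    def test_unknown_rank(self):
        rec = TaxonRecord("x", "Mammalia", "Rodentia", "F", "G", "S", False)
        with pytest.raises(ValueError, match="unknown rank"):
            rec.rank_label("kingdom")


class TestTaxonomyIO:
    def test_read_counts_and_flags(self, tmp_path):
        path = tmp_path / "tax.csv"
        path.write_text(TAXONOMY_CSV)
        tax = read_taxonomy_table(path)
        assert len(tax) == 3
        assert sorted(tax.carnivores) == ["coyote", "red_fox"]

    def test_duplicate_taxon_named_in_error(self, tmp_path):
        path = tmp_path / "tax.csv"
        path.write_text(TAXONOMY_CSV + "vole,Mammalia,Rodentia,Cricetidae,Myodes,Myodes californicus,false\n")
        with pytest.raises(ValueError, match="vole"):
            read_taxonomy_table(path)

    def test_flag_on_non_carnivore_rejected(self, tmp_path):
        path = tmp_path / "tax.csv"
        path.write_text(TAXONOMY_CSV.replace("Myodes californicus,false", "Myodes californicus,true"))
        with pytest.raises(ValueError):
            read_taxonomy_table(path)

    def test_tsv_accepted(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(TAXONOMY_CSV.replace(",", "\t"))
        assert len(read_taxonomy_table(path)) == 3

    def test_column_map(self, tmp_path):
        path = tmp_path / "tax.csv"
        path.write_text(TAXONOMY_CSV.replace("taxon_id", "Taxon"))
        tax = read_taxonomy_table(path, column_map={"taxon_id": "Taxon"})
        assert "red_fox" in tax

    def test_roundtrip(self, tmp_path, taxonomy):
        path = tmp_path / "tax.csv"
        write_taxonomy_table(taxonomy, path)
        back = read_taxonomy_table(path)
        assert {t.taxon_id for t in back} == {t.taxon_id for t in taxonomy}
        assert sorted(back.carnivores) == sorted(taxonomy.carnivores)


class TestReadCountIO:
    def _write(self, tmp_path, body):
        path = tmp_path / "counts.csv"
        path.write_text("scat_id,replicate,taxon_id,reads\n" + body)
        return path

    def _taxonomy(self, tmp_path):
        p = tmp_path / "tax.csv"
        p.write_text(TAXONOMY_CSV)
        return read_taxonomy_table(p)

    def test_toy_table(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(
            tmp_path,
            "s1,1,red_fox,100\ns1,1,vole,10\ns1,2,red_fox,90\ns1,2,vole,20\ns1,3,red_fox,80\ns1,3,vole,30\n",
        )
        table = read_read_count_table(path, tax)
        assert len(table.frame) == 6
        assert table.scat_ids == ["s1"]
        assert table.replicate_counts("s1")[2] == {"red_fox": 90, "vole": 20}

    def test_unknown_taxon_rejected(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,felis_catus,100\n")
        with pytest.raises(ValueError, match="felis_catus"):
            read_read_count_table(path, tax)

    def test_negative_reads_rejected(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,vole,-5\n")
        with pytest.raises(ValueError, match="negative"):
            read_read_count_table(path, tax)

    def test_non_integer_reads_rejected(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,vole,1.5\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_read_count_table(path, tax)

    def test_duplicate_key_rejected(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,vole,5\ns1,1,vole,6\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_read_count_table(path, tax)

    def test_zero_rows_dropped(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,vole,5\ns1,1,red_fox,0\n")
        table = read_read_count_table(path, tax)
        assert len(table.frame) == 1

    def test_mixed_delimiters_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("scat_id,replicate\ttaxon_id,reads\n")
        with pytest.raises(ValueError, match="mixes"):
            read_read_count_table(path, self._taxonomy(tmp_path))

    def test_roundtrip_identity(self, tmp_path):
        tax = self._taxonomy(tmp_path)
        path = self._write(tmp_path, "s1,1,vole,5\ns2,2,red_fox,7\n")
        table = read_read_count_table(path, tax)
        out = tmp_path / "again.csv"
        write_read_count_table(table, out)
        back = read_read_count_table(out, tax)
        pd.testing.assert_frame_equal(table.frame, back.frame)


class TestFilterConfig:
    def test_defaults_valid(self):
        cfg = FilterConfig()
        assert cfg.min_reads_per_replicate == 1000
        assert cfg.min_rra == 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_rra": 0.0},
            {"exploration_rra": 0.02},  # exceeds min_rra
            {"min_replicates": 0},
            {"max_other_carnivore_share": 1.5},
            {"rra_scope": "bogus"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)

    def test_from_file_and_unknown_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("min_rra: 0.02\nseed: 7\n")
        cfg = FilterConfig.from_file(p)
        assert cfg.min_rra == 0.02 and cfg.seed == 7
        p.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            FilterConfig.from_file(p)


class TestDomainInvariants:
    def test_defecator_required_iff_status(self):
        with pytest.raises(ValueError):
            make_scat("s", {"vole": 0.5}, defecator=None)
        with pytest.raises(ValueError):
            make_scat("s", {}, defecator="red_fox", status=ScatStatus.NO_CARNIVORE)

    def test_defecator_not_in_diet(self):
        with pytest.raises(ValueError, match="defecator"):
            make_scat("s", {"red_fox": 0.5})

    def test_wpoo_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DietProfile("fox", 2, foo={"a": 0.5}, wpoo={"a": 0.4})

    def test_incidence_bounds(self):
        with pytest.raises(ValueError):
            IncidenceFrequencies(T=2, Y={"a": 3})
        f = IncidenceFrequencies(T=3, Y={"a": 3, "b": 1, "c": 2})
        assert (f.s_obs, f.q1, f.q2) == (3, 1, 1)


class TestWriteResults:
    def _curve(self):
        return RarefactionCurve(
            T=3, t_grid=[1, 2, 3], s_hat=[1.0, 5 / 3, 2.0],
            ci=[(1.0, 1.0), (1.0, 2.0), (2.0, 2.0)], chao2=2.0, q0_hat=0.0,
        )

    def _overlap(self):
        return OverlapResult(
            metric="wpoo", o_observed=0.7412345678901, observed_ci=(0.5, 0.9),
            null_mean=0.44, null_ci=(0.27, 0.64), p_value=0.002,
            n_iterations=10000, seed=42,
        )

    def test_empty_overlaps_no_crash(self, tmp_path):
        written = write_results([], [], [], {}, tmp_path)
        data = read_results_json(written["analysis_results"])
        assert data["overlaps"] == [] and data["rarefaction"] == {}

    def test_profile_table_rows(self, tmp_path):
        profile = DietProfile(
            "red_fox", 2,
            foo={"a": 0.5, "b": 0.5, "c": 1.0},
            wpoo={"a": 0.25, "b": 0.25, "c": 0.5},
        )
        written = write_results([], [profile], [], {}, tmp_path)
        df = pd.read_csv(written["diet_profile:red_fox"])
        assert len(df) == 3
        assert set(df.columns) == {"taxon", "foo", "wpoo"}

    def test_overlap_roundtrip(self, tmp_path):
        o = self._overlap()
        written = write_results([], [], [o], {"red_fox": self._curve()}, tmp_path)
        data = read_results_json(written["analysis_results"])
        back = OverlapResult.from_dict(data["overlaps"][0])
        assert back.metric == o.metric
        assert back.o_observed == pytest.approx(o.o_observed, rel=1e-11)
        assert back.null_ci == o.null_ci
        assert back.n_iterations == o.n_iterations

    def test_statuses_table(self, tmp_path):
        comps = [
            make_scat("s1", {"vole": 0.2, "hare": 0.3}),
            make_scat("s2", {}, defecator=None, status=ScatStatus.FAILED_AMPLIFICATION),
        ]
        written = write_results(comps, [], [], {}, tmp_path)
        df = pd.read_csv(written["scat_statuses"], keep_default_na=False)
        assert len(df) == 3  # two item rows + one empty status row
        assert set(df["status"]) == {"assigned", "failed_amplification"}
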