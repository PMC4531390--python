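"""Spectral counting and NSAF: filters, enumeration oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from oaphys import proteomics as pq
from conftest import make_design, psm_frame


def random_psms(design, rng, n_proteins=6, n_rows=400):
    proteins = [f"p{i}" for i in range(n_proteins)]
    peptides = {p: [f"{p}_pep{j}" for j in range(5)] for p in proteins}
    rows = []
    for _ in range(n_rows):
        p = proteins[rng.integers(n_proteins)]
        rows.append(
            {
                "peptide": peptides[p][rng.integers(5)],
                "protein_id": p,
                "probability": float(np.round(rng.random(), 3)),
                "injection_id": design.injections[rng.integers(len(design.injections))],
            }
        )
    return psm_frame(rows)


class TestParse:
    def test_round_trip(self, design, tmp_path, rng):
        df = random_psms(design, rng, n_rows=50)
        path = tmp_path / "psms.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = pq.parse_psm_table(path, design)
        pd.testing.assert_frame_equal(back, df)

    def test_header_only(self, design, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("peptide\tprotein_id\tprobability\tinjection_id\n")
        assert len(pq.parse_psm_table(path, design)) == 0

    def test_missing_column(self, design, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("peptide\tprotein_id\tprobability\nPEP\tp1\t0.99\n")
        with pytest.raises(ValueError, match="missing columns"):
            pq.parse_psm_table(path, design)

    def test_unknown_injection(self, design, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("peptide\tprotein_id\tprobability\tinjection_id\nPEP\tp1\t0.99\tnope\n")
        with pytest.raises(ValueError, match="not in design"):
            pq.parse_psm_table(path, design)

    def test_malformed_probability_reports_line(self, design, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(
            "peptide\tprotein_id\tprobability\tinjection_id\n"
            "PEP\tp1\t0.99\t400-1-inj1\nPEP\tp1\t1.7\t400-1-inj1\n"
        )
        with pytest.raises(ValueError, match=r"lines \[2\]"):
            pq.parse_psm_table(path, design)


class TestFilters:
    def test_probability_boundary_inclusive(self, design):
        df = psm_frame(
            [{"peptide": "A", "protein_id": "p", "probability": p, "injection_id": "400-1-inj1"}
             for p in (0.89, 0.90, 0.95)]
        )
        assert len(pq.filter_psms(df)) == 2

    def test_empty_input(self, design):
        assert len(pq.filter_psms(psm_frame([]))) == 0

    def test_filter_matches_enumeration(self, design, rng):
        df = random_psms(design, rng)
        kept = pq.filter_psms(df, 0.9)
        assert len(kept) == sum(1 for p in df["probability"] if p >= 0.9)

    def test_low_evidence_floor_boundary(self, design):
        rows = []
        for i in range(7):
            rows.append({"peptide": f"a{i}", "protein_id": "seven", "probability": 1.0,
                         "injection_id": "400-1-inj1"})
        for i in range(8):
            rows.append({"peptide": f"b{i}", "protein_id": "eight", "probability": 1.0,
                         "injection_id": "400-1-inj1"})
        matrix = pq.count_spectra(psm_frame(rows), design)
        filtered = pq.filter_low_evidence_proteins(matrix, 8)
        assert list(filtered.proteins) == ["eight"]

    def test_all_below_floor_gives_empty(self, design):
        rows = [{"peptide": "a", "protein_id": "p", "probability": 1.0, "injection_id": "400-1-inj1"}]
        matrix = pq.count_spectra(psm_frame(rows), design)
        assert len(pq.filter_low_evidence_proteins(matrix, 8).proteins) == 0

    def test_pipeline_idempotent(self, design, rng):
        df = pq.filter_psms(random_psms(design, rng), 0.9)
        once = pq.filter_low_evidence_proteins(pq.count_spectra(df, design), 8)
        twice = pq.filter_low_evidence_proteins(once, 8)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        pd.testing.assert_frame_equal(pq.filter_psms(df, 0.9), df)


class TestCounts:
    def test_single_psm(self, design):
        m = pq.count_spectra(
            psm_frame([{"peptide": "A", "protein_id": "p", "probability": 1.0,
                        "injection_id": "400-1-inj1"}]), design)
        assert m.counts.loc["p", "400-1-inj1"] == 1
        assert m.counts.to_numpy().sum() == 1

    def test_repeat_peptide_counts_twice(self, design):
        rows = [{"peptide": "A", "protein_id": "p", "probability": 1.0, "injection_id": "400-1-inj1"}] * 2
        m = pq.count_spectra(psm_frame(rows), design)
        assert m.counts.loc["p", "400-1-inj1"] == 2
        assert m.unique_peptides.loc["p", "400-1"] == 1

    def test_counts_match_brute_force(self, design, rng):
        df = random_psms(design, rng)
        m = pq.count_spectra(df, design)
        inj_to_oyster = design.injection_to_oyster().to_dict()
        # brute-force enumeration with plain dicts
        counts, uniq = {}, {}
        for r in df.itertuples(index=False):
            counts[(r.protein_id, r.injection_id)] = counts.get((r.protein_id, r.injection_id), 0) + 1
            uniq.setdefault((r.protein_id, inj_to_oyster[r.injection_id]), set()).add(r.peptide)
        for (p, inj), n in counts.items():
            assert m.counts.loc[p, inj] == n
        assert m.counts.to_numpy().sum() == len(df)
        for (p, o), peps in uniq.items():
            assert m.unique_peptides.loc[p, o] == len(peps)

    def test_unique_le_total_per_oyster(self, design, rng):
        m = pq.count_spectra(random_psms(design, rng), design)
        per_oyster = m.counts.T.groupby(design.injection_to_oyster()).sum().T
        per_oyster = per_oyster[m.unique_peptides.columns]
        assert (m.unique_peptides <= per_oyster).all().all()


class TestMaskAndNsaf:
    def test_mask_boundary(self, design):
        rows = [
            {"peptide": "A", "protein_id": "one", "probability": 1.0, "injection_id": "400-1-inj1"},
            {"peptide": "A", "protein_id": "two", "probability": 1.0, "injection_id": "400-1-inj1"},
            {"peptide": "B", "protein_id": "two", "probability": 1.0, "injection_id": "400-1-inj2"},
        ]
        m = pq.count_spectra(psm_frame(rows), design)
        mask = pq.expression_mask(m, 2)
        assert not mask.loc["one", "400-1"]  # 1 unique peptide → zeroed
        assert mask.loc["two", "400-1"]      # 2 unique peptides across injections

    def test_single_protein_nsaf_is_one(self, design):
        rows = [{"peptide": f"A{i}", "protein_id": "p", "probability": 1.0,
                 "injection_id": "400-1-inj1"} for i in range(3)]
        m = pq.count_spectra(psm_frame(rows), design)
        nsaf = pq.compute_nsaf(m, pd.Series({"p": 250.0}))
        assert nsaf.values.loc["p", "400-1"] == pytest.approx(1.0)

    def test_length_normalization_ratio(self, design):
        # equal average SpC, lengths 100 and 300 → NSAF 0.75 / 0.25
        rows = []
        for pid in ("short", "long"):
            for i in range(2):
                rows.append({"peptide": f"{pid}{i}", "protein_id": pid, "probability": 1.0,
                             "injection_id": "400-1-inj1"})
        m = pq.count_spectra(psm_frame(rows), design)
        nsaf = pq.compute_nsaf(m, pd.Series({"short": 100.0, "long": 300.0}))
        assert nsaf.values.loc["short", "400-1"] == pytest.approx(0.75)
        assert nsaf.values.loc["long", "400-1"] == pytest.approx(0.25)

    def test_missing_length_raises(self, design):
        rows = [{"peptide": "A", "protein_id": "p", "probability": 1.0, "injection_id": "400-1-inj1"}]
        m = pq.count_spectra(psm_frame(rows), design)
        with pytest.raises(ValueError, match="missing protein lengths"):
            pq.compute_nsaf(m, pd.Series({"other": 100.0}))

    def _random_nsaf(self, design, rng):
        df = random_psms(design, rng, n_proteins=8, n_rows=600)
        lengths = pd.Series({f"p{i}": float(rng.integers(100, 500)) for i in range(8)})
        return df, lengths, pq.nsaf_pipeline(df, design, lengths)

    def test_nsaf_matches_spreadsheet_recomputation(self, design, rng):
        df, lengths, nsaf = self._random_nsaf(design, rng)
        kept = df[df["probability"] >= 0.9]
        inj_to_oyster = design.injection_to_oyster().to_dict()
        injections_of = {o: [i for i, oo in inj_to_oyster.items() if oo == o] for o in design.oysters}
        totals = kept.groupby("protein_id").size()
        retained = [p for p in totals.index if totals[p] >= 8]
        for oyster in design.oysters:
            saf = {}
            for p in retained:
                sub = kept[(kept["protein_id"] == p) & (kept["injection_id"].isin(injections_of[oyster]))]
                if sub["peptide"].nunique() >= 2:
                    avg = len(sub) / len(injections_of[oyster])
                    saf[p] = avg / lengths[p]
                else:
                    saf[p] = 0.0
            denom = sum(saf.values())
            for p in retained:
                expected = saf[p] / denom if denom else 0.0
                assert nsaf.values.loc[p, oyster] == pytest.approx(expected, abs=1e-12)

    def test_columns_sum_to_one(self, design, rng):
        _, _, nsaf = self._random_nsaf(design, rng)
        sums = nsaf.values.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_row_permutation_invariance(self, design, rng):
        df, lengths, nsaf = self._random_nsaf(design, rng)
        perm = df.sample(frac=1.0, random_state=7)
        nsaf2 = pq.nsaf_pipeline(perm, design, lengths)
        pd.testing.assert_frame_equal(
            nsaf.values.sort_index(), nsaf2.values.sort_index(), check_exact=False, atol=1e-14
        )

    def test_per_oyster_scale_invariance(self, design, rng):
        """Duplicating every PSM of one oyster leaves that oyster's NSAF unchanged."""
        df, lengths, nsaf = self._random_nsaf(design, rng)
        target = "400-1"
        i2o = design.injection_to_oyster()
        inj = set(i2o.index[i2o == target])
        extra = df[df["injection_id"].isin(inj)]
        dup = pd.concat([df, extra, extra], ignore_index=True)
        nsaf2 = pq.nsaf_pipeline(dup, design, lengths)
        common = nsaf.values.index.intersection(nsaf2.values.index)
        expressed = nsaf.mask.loc[common, target] & nsaf2.mask.loc[common, target]
        a = nsaf.values.loc[common, target][expressed]
        b = nsaf2.values.loc[common, target][expressed]
        # proteins expressed in both runs keep identical relative abundance
        np.testing.assert_allclose(a / a.sum(), b / b.sum(), atol=1e-12)


def test_read_protein_lengths_fasta_and_tsv(tmp_path):
    fasta = tmp_path / "prot.fasta"
    fasta.write_text(">p1 desc\nMKV\n>p2\nMKVAW\n")
    s = pq.read_protein_lengths(fasta)
    assert s["p1"] == 3 and s["p2"] == 5
    tsv = tmp_path / "prot.tsv"
    tsv.write_text("protein_id\tlength\np1\t120\n")
    assert pq.read_protein_lengths(tsv)["p1"] == 120
    bad = tmp_path / "bad.tsv"
    bad.write_text("protein_id\tlength\np1\t0\n")
    with pytest.raises(ValueError, match="positive"):
        pq.read_protein_lengths(bad)


def test_design_validation():
    df = make_design().table.copy()
    df.loc[0, "treatment"] = "other"
    with pytest.raises(ValueError, match="multiple treatments"):
        pq.InjectionDesign(df)
    with pytest.warns(UserWarning, match="expected 3"):
        make_design(injections_per=2)
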