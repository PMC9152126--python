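"""CID matching, read filters, UMI collapsing, and the demux pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stereopipe as spp
from stereopipe.demux import BarcodeWhitelist, hamming, write_reads_tsv, read_reads_tsv


@pytest.fixture
def wl_simple():
    return BarcodeWhitelist({"AAAA": (0, 0), "CCCC": (1, 1)})


class TestMatchCid:
    def test_exact_hit(self, wl_simple):
        assert spp.match_cid("AAAA", wl_simple) == (0, 0)

    def test_unique_one_mismatch_rescue(self, wl_simple):
        assert spp.match_cid("AAAT", wl_simple) == (0, 0)

    def test_ambiguous_rescue_unassigned(self):
        wl = BarcodeWhitelist({"AAAA": (0, 0), "AAAT": (0, 1)})
        assert spp.match_cid("AAAG", wl) is None

    def test_no_candidate_unassigned(self, wl_simple):
        assert spp.match_cid("GGGG", wl_simple) is None

    def test_length_mismatch_raises(self, wl_simple):
        with pytest.raises(ValueError, match="length"):
            spp.match_cid("AAAAA", wl_simple)

    def test_matches_brute_force_on_random_whitelists(self, rng):
        """Exact + unique-Hamming-1 rule vs exhaustive scan, random cases."""
        bases = "ACGT"
        for _ in range(200):
            seqs = set()
            while len(seqs) < 8:
                seqs.add("".join(rng.choice(list(bases), 5)))
            wl = BarcodeWhitelist({s: (i, 0) for i, s in enumerate(sorted(seqs))})
            obs = "".join(rng.choice(list(bases), 5))
            if obs in wl.mapping:
                expect = wl.mapping[obs]
            else:
                hits = {wl.mapping[s] for s in wl.mapping if hamming(obs, s) == 1}
                expect = hits.pop() if len(hits) == 1 else None
            assert spp.match_cid(obs, wl) == expect


class TestFilters:
    @pytest.mark.parametrize(
        "umi,quals,keep",
        [
            ("ANAA", [30, 30, 30, 30], False),  # any N rejects
            ("AAAA", [9, 9, 9, 30], False),  # three bases under Q10
            ("AAAA", [9, 9, 30, 30], True),  # exactly two low bases kept
            ("AAAA", [10, 10, 10, 10], True),  # Q10 itself is not "lower than 10"
        ],
    )
    def test_umi_quality_boundaries(self, umi, quals, keep):
        assert spp.filter_umi(umi, quals) is keep

    def test_umi_length_mismatch(self):
        with pytest.raises(ValueError):
            spp.filter_umi("AAA", [30, 30])

    @pytest.mark.parametrize("mapq,keep", [(9, False), (10, True), (None, True)])
    def test_mapq_boundary(self, mapq, keep):
        assert spp.filter_mapq(mapq) is keep


class TestCollapseUmis:
    def test_examples(self):
        assert spp.collapse_umis([]) == 0
        assert spp.collapse_umis(["AAAA", "AAAT", "TTTT"]) == 2
        assert spp.collapse_umis(["AAAA"] * 5) == 1

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            spp.collapse_umis(["AAAA", "AAA"])

    def test_chain_collapses_to_one(self):
        # AAAA-AAAT-AAGT-ACGT: consecutive Hamming-1 links form one component
        assert spp.collapse_umis(["AAAA", "AAAT", "AAGT", "ACGT"]) == 1

    def test_matches_union_find_oracle(self, rng):
        """1,000 random groups (<= 20 UMIs, length 6) vs brute force."""
        assert _collapse_oracle_agreement(rng, 1000) == 1.0


def brute_force_components(umis):
    """O(n^2) union-find over pairwise Hamming <= 1; the independent oracle."""
    nodes = sorted(set(umis))
    parent = {u: u for u in nodes}

    def find(u):
        while parent[u] != u:
            u = parent[u]
        return u

    for a, b in itertools.combinations(nodes, 2):
        if sum(x != y for x, y in zip(a, b)) <= 1:
            parent[find(a)] = find(b)
    return len({find(u) for u in nodes})


def _collapse_oracle_agreement(rng, n_groups):
    bases = np.array(list("ACGT"))
    agree = 0
    for _ in range(n_groups):
        n = int(rng.integers(0, 21))
        umis = ["".join(rng.choice(bases, 6)) for _ in range(n)]
        agree += spp.collapse_umis(umis) == brute_force_components(umis)
    return agree / n_groups


class TestPipeline:
    def test_error_free_round_trip(self, small_tissue):
        """demux(generate_reads(M, error=0)) reproduces M exactly."""
        _, matrix, _ = small_tissue
        wl = spp.make_whitelist(40, 40)
        reads, _ = spp.generate_reads(matrix, wl, cid_error_rate=0.0, seed=0)
        rebuilt, report = spp.build_spot_matrix(reads, wl)
        assert rebuilt.equals(matrix)
        assert report.reads_assigned == len(reads)

    def test_rejected_umi_accounting(self):
        wl = BarcodeWhitelist({"AAAA": (0, 0)})
        reads = pd.DataFrame(
            {
                "cid": ["AAAA", "AAAA"],
                "umi": ["CCCC", "CNCC"],
                "umi_quals": ["IIII", "IIII"],
                "gene": ["g", "g"],
            }
        )
        matrix, report = spp.build_spot_matrix(reads, wl)
        assert report.rejected_umi == 1
        assert matrix.total_umi == 1
        assert report.check_accounting()

    def test_mapq_filter_and_accounting(self):
        wl = BarcodeWhitelist({"AAAA": (0, 0)})
        reads = pd.DataFrame(
            {
                "cid": ["AAAA"] * 3 + ["AAAAA"],
                "umi": ["CCCC", "GGGG", "TTTT", "CCCC"],
                "umi_quals": ["IIII"] * 4,
                "gene": ["g"] * 4,
                "mapq": pd.array([9, 10, None, 30], dtype="Int64"),
            }
        )
        matrix, report = spp.build_spot_matrix(reads, wl)
        assert report.rejected_mapq == 1
        assert report.rejected_cid_length == 1
        assert matrix.total_umi == 2  # GGGG + TTTT (distance 2 apart)
        assert report.check_accounting()

    def test_mutated_reads_recovered_with_distance3_whitelist(self, small_tissue):
        _, matrix, _ = small_tissue
        wl = spp.make_whitelist(40, 40)
        reads, truth = spp.generate_reads(matrix, wl, cid_error_rate=0.1, seed=3)
        assigned, report = spp.demultiplex(reads, wl)
        merged = assigned.join(truth, rsuffix="_true")
        mutated = merged[truth.loc[merged.index, "cid_mutated"]]
        correct = (
            (mutated["x"] == mutated["x_true"]) & (mutated["y"] == mutated["y_true"])
        ).mean()
        assert correct >= 0.99

    def test_mapq_threshold_monotonicity(self, rng):
        """On generator-style reads, lowering min MAPQ never lowers a count."""
        spec = spp.TissueSimSpec(grid_width=8, grid_height=8, n_genes=10,
                                 markers_per_region=1, seed=2)
        matrix, _ = spp.generate_expression(spec)
        wl = spp.make_whitelist(8, 8)
        reads, _ = spp.generate_reads(matrix, wl, seed=2)
        reads = reads.copy()
        reads["mapq"] = pd.array(rng.integers(0, 60, len(reads)), dtype="Int64")
        strict, _ = spp.build_spot_matrix(reads, wl, min_mapq=30)
        loose, _ = spp.build_spot_matrix(reads, wl, min_mapq=0)
        s = strict.records.set_index(["geneID", "x", "y"])["MIDCount"]
        l = loose.records.set_index(["geneID", "x", "y"])["MIDCount"]
        joined = s.to_frame("strict").join(l.to_frame("loose"), how="left")
        assert (joined["loose"] >= joined["strict"]).all()

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            BarcodeWhitelist({})


class TestReadIO:
    def test_tsv_round_trip(self, tmp_path):
        reads = pd.DataFrame(
            {
                "cid": ["AAAA"],
                "umi": ["CCCC"],
                "umi_quals": ["IIII"],
                "gene": ["g1"],
                "mapq": pd.array([pd.NA], dtype="Int64"),
            }
        )
        write_reads_tsv(reads, tmp_path / "r.tsv")
        back = read_reads_tsv(tmp_path / "r.tsv")
        assert back["cid"].tolist() == ["AAAA"]
        assert back["mapq"].isna().all()

    def test_sam_dialect(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 1000, "SN": "chr1"}]}
        path = tmp_path / "reads.sam"
        with pysam.AlignmentFile(path, "w", header=header) as out:
            a = pysam.AlignedSegment()
            a.query_name = "r1"
            a.query_sequence = "ACGTACGT"
            a.reference_id = 0
            a.reference_start = 10
            a.cigarstring = "8M"
            a.mapping_quality = 42
            a.set_tag("CB", "AAAA")
            a.set_tag("UB", "CCCC")
            a.set_tag("UY", "IIII")
            a.set_tag("GE", "g1")
            out.write(a)
        from stereopipe.demux import read_reads_sam

        df = read_reads_sam(path)
        assert df.iloc[0].tolist() == ["AAAA", "CCCC", "IIII", "g1", 42]
        wl = BarcodeWhitelist({"AAAA": (2, 3)})
        matrix, report = spp.build_spot_matrix(df, wl)
        assert matrix.records.iloc[0].tolist() == ["g1", 2, 3, 1]
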