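"""Atlas schema, hemisphere mirroring, and region aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strokeconn.atlas import AtlasSchemaError, PatchAtlas, load_patch_atlas
from strokeconn.io import SchemaError, read_links, write_links
from strokeconn.links import (
    FPC_VIEW_REGIONS,
    RegionPairCounts,
    aggregate_to_regions,
    collapse_to_fpc,
    mirror_for_lesion,
)


class TestAtlas:
    def test_default_atlas_shape(self, atlas):
        assert len(atlas.patch_ids) == 84
        assert len(atlas.regions) == 22
        left = [r for r in atlas.regions if r.startswith("L.")]
        right = [r for r in atlas.regions if r.startswith("R.")]
        assert len(left) == len(right) == 11

    def test_fpc_present_both_hemispheres(self, atlas):
        for hemi in ("L", "R"):
            patches = atlas.patches_in_region(f"{hemi}.fpc")
            assert len(patches) >= 1
            assert all(atlas.is_fpc(p) for p in patches)

    def test_wrong_patch_count_rejected(self, atlas, tmp_path):
        bad = atlas.table.iloc[:-1]
        path = tmp_path / "bad.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(AtlasSchemaError, match="84"):
            load_patch_atlas(path)

    def test_unknown_hemisphere_rejected(self, atlas):
        bad = atlas.table.copy()
        bad.loc[3, "hemisphere"] = "center"
        with pytest.raises(AtlasSchemaError, match="row 3"):
            PatchAtlas(bad)

    def test_missing_fpc_rejected(self, atlas):
        bad = atlas.table.copy()
        bad.loc[bad["region"] == "fpc", "region"] = "insula"
        with pytest.raises(AtlasSchemaError):
            PatchAtlas(bad)

    def test_unknown_patch_lookup(self, atlas):
        with pytest.raises(KeyError):
            atlas.region_of("L99")


def _links(rows):
    return pd.DataFrame(
        rows, columns=["subject", "visit", "trial", "src_patch", "dst_patch"]
    )


class TestMirroring:
    subjects = pd.DataFrame(
        {"subject": ["a", "b"], "lesion_hemisphere": ["left", "right"]}
    )

    def test_right_lesion_patches_flip(self):
        links = _links([("b", 1, 1, "R07", "L13")])
        out = mirror_for_lesion(links, self.subjects)
        assert out.loc[0, "src_patch"] == "L07"
        assert out.loc[0, "dst_patch"] == "R13"

    def test_left_lesion_unchanged(self):
        links = _links([("a", 1, 1, "R07", "L13")])
        out = mirror_for_lesion(links, self.subjects)
        pd.testing.assert_frame_equal(out, links)

    def test_involution(self):
        links = _links([("b", 2, 1, "L00", "R41"), ("b", 1, 2, "R10", "R11")])
        twice = mirror_for_lesion(mirror_for_lesion(links, self.subjects), self.subjects)
        pd.testing.assert_frame_equal(twice, links)

    def test_missing_subject_raises(self):
        links = _links([("zzz", 1, 1, "L00", "L01")])
        with pytest.raises(KeyError, match="zzz"):
            mirror_for_lesion(links, self.subjects)


class TestAggregation:
    def test_empty_trial_absent_and_zero_matrix(self, atlas):
        links = _links([])
        out = aggregate_to_regions(links, atlas)
        assert out.n_trials == 0

    def test_counting_into_single_cell(self, atlas):
        fpc = atlas.patches_in_region("L.fpc")
        ins = atlas.patches_in_region("R.insula")
        links = _links([("a", 1, 1, fpc[0], ins[0])] * 3)
        out = aggregate_to_regions(links, atlas)
        i = out.regions.index("L.fpc")
        j = out.regions.index("R.insula")
        assert out.counts[0, i, j] == 3
        assert out.total() == 3

    def test_total_conservation_random_links(self, atlas):
        rng = np.random.default_rng(5)
        patches = atlas.patch_ids
        rows = [
            ("s", int(rng.integers(1, 3)), 1, rng.choice(patches), rng.choice(patches))
            for _ in range(1000)
        ]
        out = aggregate_to_regions(_links(rows), atlas)
        assert out.total() == 1000

    def test_self_links_on_diagonal(self, atlas):
        fpc = atlas.patches_in_region("L.fpc")
        links = _links([("a", 1, 1, fpc[0], fpc[1])])
        out = aggregate_to_regions(links, atlas)
        i = out.regions.index("L.fpc")
        assert out.counts[0, i, i] == 1

    def test_unknown_patch_raises(self, atlas):
        with pytest.raises(KeyError):
            aggregate_to_regions(_links([("a", 1, 1, "X00", "L01")]), atlas)

    def test_mirror_commutes_with_aggregation(self, atlas, links_small):
        """Mirror-then-aggregate equals aggregate-then-relabel-hemispheres."""
        cohort, links = links_small
        agg_mirrored = aggregate_to_regions(mirror_for_lesion(links, cohort), atlas)
        agg_raw = aggregate_to_regions(links, atlas)
        swap = {r: ("R" if r[0] == "L" else "L") + r[1:] for r in agg_raw.regions}
        perm = [agg_raw.regions.index(swap[r]) for r in agg_raw.regions]
        lesion = dict(zip(cohort["subject"], cohort["lesion_hemisphere"]))
        for k, key in enumerate(agg_raw.index.itertuples(index=False)):
            expected = agg_raw.counts[k]
            if lesion[key.subject] == "right":
                expected = expected[np.ix_(perm, perm)]
            k2 = agg_mirrored.index.query(
                "subject == @key.subject and visit == @key.visit and trial == @key.trial"
            ).index[0]
            np.testing.assert_array_equal(agg_mirrored.counts[k2], expected)


class TestFpcCollapse:
    def test_all_zero(self, atlas):
        counts = RegionPairCounts(
            index=pd.DataFrame({"subject": ["a"], "visit": [1], "trial": [1]}),
            counts=np.zeros((1, 22, 22), dtype=int),
            regions=atlas.regions,
        )
        out = collapse_to_fpc(counts)
        assert out.regions == FPC_VIEW_REGIONS
        assert out.total() == 0

    def test_cell_routing(self, atlas):
        regions = atlas.regions
        mats = np.zeros((1, 22, 22), dtype=int)
        i = regions.index("L.fpc")
        j = regions.index("R.insula")  # contralesional non-FPC
        mats[0, i, j] = 5
        counts = RegionPairCounts(
            index=pd.DataFrame({"subject": ["a"], "visit": [1], "trial": [1]}),
            counts=mats,
            regions=regions,
        )
        out = collapse_to_fpc(counts)
        assert out.counts[0, 0, 3] == 5  # Ipsi FPC -> Contra ALL
        assert out.total() == 5

    def test_conservation_random(self, atlas):
        rng = np.random.default_rng(9)
        mats = rng.integers(0, 5, size=(3, 22, 22))
        counts = RegionPairCounts(
            index=pd.DataFrame(
                {"subject": ["a", "a", "b"], "visit": [1, 2, 1], "trial": [1, 1, 1]}
            ),
            counts=mats,
            regions=atlas.regions,
        )
        out = collapse_to_fpc(counts)
        assert out.total() == counts.total()
        assert out.counts.shape == (3, 4, 4)


class TestLinkIO:
    def test_round_trip_simple(self, tmp_path):
        links = _links([("a", 1, 1, "L00", "R41"), ("b", 2, 3, "R00", "L13")])
        path = tmp_path / "links.tsv"
        write_links(links, path)
        back = read_links(path)
        pd.testing.assert_frame_equal(back, links)

    def test_bad_visit_rejected(self, tmp_path):
        links = _links([("a", 1, 1, "L00", "L01"), ("a", 3, 1, "L00", "L01")])
        path = tmp_path / "links.tsv"
        write_links(links, path)
        with pytest.raises(SchemaError, match="row 1"):
            read_links(path)

    def test_bad_patch_rejected(self, tmp_path):
        links = _links([("a", 1, 1, "L99", "L01")])
        path = tmp_path / "links.tsv"
        write_links(links, path)
        with pytest.raises(SchemaError, match="L99"):
            read_links(path)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2", "s3"]),
                st.sampled_from([1, 2]),
                st.integers(1, 4),
                st.integers(0, 41),
                st.integers(0, 41),
                st.sampled_from(["L", "R"]),
                st.sampled_from(["L", "R"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_round_trip_fuzzed(self, tmp_path_factory, rows):
        links = _links(
            [
                (s, v, t, f"{h1}{a:02d}", f"{h2}{b:02d}")
                for s, v, t, a, b, h1, h2 in rows
            ]
        )
        path = tmp_path_factory.mktemp("fuzz") / "links.tsv"
        write_links(links, path)
        back = read_links(path)
        pd.testing.assert_frame_equal(back, links)
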