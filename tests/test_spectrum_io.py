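import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectrotype.errors import FormatError, ValidationError
from spectrotype.spectrum_io import (
    PeakList,
    Spectrum,
    default_meta,
    read_library,
    read_newick,
    read_peaklist,
    read_spectrum,
    write_library,
    write_newick,
    write_peaklist,
    write_spectrum,
)

from conftest import minimal_mzml


class TestSpectrumXY:
    def test_identity_read_back(self, tmp_path):
        path = tmp_path / "five.xy"
        path.write_text("# strain_id: X\n3000 1.0\n3001 2\n3002 3\n3003 2\n3004 1\n")
        s = read_spectrum(path)
        assert len(s) == 5
        assert s.meta["strain_id"] == "X"
        assert s.meta["species"] == "unknown"

    def test_descending_mz_rejected(self, tmp_path):
        path = tmp_path / "bad.xy"
        path.write_text("3000 1.0\n2999 2.0\n")
        with pytest.raises(ValidationError, match="ascending"):
            read_spectrum(path)

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.xy"
        path.write_text("3000 1.0\n3001 oops\n")
        with pytest.raises(FormatError, match="line 2"):
            read_spectrum(path)

    def test_round_trip(self, tmp_path, simple_spectrum):
        path = tmp_path / "s.xy"
        write_spectrum(simple_spectrum, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.mz, simple_spectrum.mz, atol=1e-9)
        np.testing.assert_allclose(back.intensity, simple_spectrum.intensity, atol=1e-9)

    def test_negative_intensities_preserved_on_read(self, tmp_path):
        path = tmp_path / "neg.xy"
        path.write_text("3000 -0.5\n3001 1.0\n")
        s = read_spectrum(path)
        assert s.intensity[0] == -0.5


class TestMzML:
    def test_round_trip_against_encoded_arrays(self, tmp_path):
        mz = np.array([3000.0, 3500.5, 4000.0, 4500.0, 5000.0])
        inten = np.array([0.1, 0.9, 0.3, 0.0, 0.2])
        path = tmp_path / "one.mzML"
        path.write_text(minimal_mzml(mz, inten))
        s = read_spectrum(path)
        np.testing.assert_allclose(s.mz, mz)
        np.testing.assert_allclose(s.intensity, inten)
        assert s.meta["source_id"] == "scan=1"

    def test_garbage_xml_is_format_error(self, tmp_path):
        path = tmp_path / "bad.mzML"
        path.write_text("<mzML><broken")
        with pytest.raises(FormatError):
            read_spectrum(path)


class TestPeakListTSV:
    def test_empty_round_trip(self, tmp_path):
        pl = PeakList(np.array([]), np.array([]), np.array([]))
        path = tmp_path / "empty.tsv"
        write_peaklist(pl, path)
        assert len(read_peaklist(path)) == 0

    def test_three_rows(self, tmp_path, three_peak_list):
        path = tmp_path / "pl.tsv"
        write_peaklist(three_peak_list, path)
        data_rows = [
            ln for ln in path.read_text().splitlines()
            if ln and not ln.startswith("#") and not ln.startswith("mz")
        ]
        assert len(data_rows) == 3

    def test_round_trip_and_meta(self, tmp_path, three_peak_list):
        path = tmp_path / "pl.tsv"
        write_peaklist(three_peak_list, path)
        back = read_peaklist(path)
        np.testing.assert_allclose(back.mz, three_peak_list.mz, atol=1e-6)
        np.testing.assert_allclose(back.rel_intensity, three_peak_list.rel_intensity, atol=1e-6)
        assert back.meta["species"] == "sp1"
        assert back.meta["bio_rep"] == 0

    def test_invariant_violations_listed(self):
        with pytest.raises(ValidationError, match="floor"):
            PeakList(np.array([5000.0, 6000.0]), np.array([1.0, 0.01]), np.ones(2))
        with pytest.raises(ValidationError, match="outside"):
            PeakList(np.array([2000.0]), np.array([1.0]), np.ones(1))
        with pytest.raises(ValidationError, match="cap"):
            PeakList(
                np.linspace(4000, 14000, 101), np.ones(101), np.ones(101)
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_valid_lists_round_trip(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 30))
        mz = np.sort(
            np.array(
                data.draw(
                    st.lists(
                        st.floats(3000, 15000, allow_nan=False),
                        min_size=n, max_size=n, unique=True,
                    )
                )
            )
        )
        rel = np.array(data.draw(st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n)))
        rel[data.draw(st.integers(0, n - 1))] = 1.0
        pl = PeakList(mz, rel, np.ones(n))
        path = tmp_path_factory.mktemp("rt") / "pl.tsv"
        write_peaklist(pl, path)
        back = read_peaklist(path)
        np.testing.assert_allclose(back.mz, pl.mz, atol=1e-6)
        np.testing.assert_allclose(back.rel_intensity, pl.rel_intensity, atol=1e-6)


class TestLibraryJSON:
    @staticmethod
    def _library(n_entries=1):
        from spectrotype.library import build_main_spectrum, build_library

        msps = []
        for i in range(n_entries):
            mz = np.array([4000.0 + 100 * i, 6000.0, 9000.0 + 50 * i])
            pl = PeakList(mz, np.array([0.5, 1.0, 0.25]), np.ones(3),
                          default_meta(strain_id=f"S{i}", species=f"sp{i}", genus="G"))
            msps.append(
                build_main_spectrum([pl, pl], label=f"S{i}", genus="G", species=f"sp{i}")
            )
        return build_library(msps, "species")

    def test_one_entry_round_trip(self, tmp_path):
        lib = self._library(1)
        path = tmp_path / "lib.json"
        write_library(lib, path)
        back = read_library(path)
        assert back.level == "species"
        assert len(back) == 1
        np.testing.assert_array_equal(back.entries[0].mz, lib.entries[0].mz)
        np.testing.assert_allclose(
            back.entries[0].mean_rel_intensity, lib.entries[0].mean_rel_intensity
        )

    def test_five_entries_order_preserved(self, tmp_path):
        lib = self._library(5)
        path = tmp_path / "lib.json"
        write_library(lib, path)
        back = read_library(path)
        assert [e.label for e in back.entries] == [e.label for e in lib.entries]

    def test_round_trip_scores_identical(self, tmp_path, three_peak_list):
        from spectrotype.similarity import log_score

        lib = self._library(3)
        path = tmp_path / "lib.json"
        write_library(lib, path)
        back = read_library(path)
        for a, b in zip(lib.entries, back.entries):
            sa = log_score(three_peak_list, a)
            sb = log_score(three_peak_list, b)
            assert sa.log_score == sb.log_score

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "other/9", "entries": []}')
        with pytest.raises(FormatError, match="schema"):
            read_library(path)


class TestNewick:
    def test_two_leaf_tree(self, tmp_path):
        from spectrotype.taxonomy import upgma

        tree = upgma(np.array([[0.0, 2.0], [2.0, 0.0]]), ["A", "B"])
        text = write_newick(tree)
        assert text == "(A:1.000000,B:1.000000);"

    def test_three_leaf_parses_with_independent_reader(self, tmp_path):
        import dendropy

        from spectrotype.taxonomy import bootstrap_support, binary_matrix
        from spectrotype.library import MainSpectrum

        msps = [
            MainSpectrum("A", "strain", np.array([4000, 5000]), np.ones(2), np.ones(2), 2),
            MainSpectrum("B", "strain", np.array([4000, 5000]), np.ones(2), np.ones(2), 2),
            MainSpectrum("C", "strain", np.array([9000, 11000]), np.ones(2), np.ones(2), 2),
        ]
        tree = bootstrap_support(binary_matrix(msps), n_reps=10, seed=1)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        dtree = dendropy.Tree.get(path=str(path), schema="newick")
        assert {leaf.taxon.label for leaf in dtree.leaf_node_iter()} == {"A", "B", "C"}
        internal_labels = [
            n.label for n in dtree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert len(internal_labels) == 1  # one supported internal node

    def test_empty_tree_errors(self):
        from spectrotype.taxonomy import Node

        with pytest.raises(ValidationError):
            write_newick(Node())

    def test_read_back(self, tmp_path):
        from spectrotype.taxonomy import upgma, compare_topology

        d = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0.0]])
        tree = upgma(d, ["A", "B", "C", "D"])
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert compare_topology(tree, back)["rf_distance"] == 0
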