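"""Track reading and branch splitting."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alskit import simulate, track_io


def _trackmate_xml(spatialunits="micron", timeunits="s", pixelwidth=None, bad_edge=False):
    """Minimal synthetic TrackMate document: 3 spots, 2 edges, 1 track."""
    calib = (
        f'<Settings><ImageData pixelwidth="{pixelwidth}" pixelheight="{pixelwidth}"/></Settings>'
        if pixelwidth is not None
        else ""
    )
    dangling = '<Edge SPOT_SOURCE_ID="2" SPOT_TARGET_ID="99"/>' if bad_edge else ""
    return textwrap.dedent(
        f"""\
        <TrackMate version="7.0.0">
          <Model spatialunits="{spatialunits}" timeunits="{timeunits}">
            <AllSpots nspots="3">
              <SpotsInFrame frame="0">
                <Spot ID="1" FRAME="0" POSITION_X="2.0" POSITION_Y="4.0" POSITION_Z="0.0" POSITION_T="0.0" QUALITY="1.0"/>
              </SpotsInFrame>
              <SpotsInFrame frame="1">
                <Spot ID="2" FRAME="1" POSITION_X="2.5" POSITION_Y="4.0" POSITION_Z="0.0" POSITION_T="2.0" QUALITY="1.0"/>
              </SpotsInFrame>
              <SpotsInFrame frame="2">
                <Spot ID="3" FRAME="2" POSITION_X="3.0" POSITION_Y="4.0" POSITION_Z="0.0" POSITION_T="4.0" QUALITY="1.0"/>
              </SpotsInFrame>
            </AllSpots>
            <AllTracks>
              <Track TRACK_ID="0">
                <Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="2"/>
                <Edge SPOT_SOURCE_ID="2" SPOT_TARGET_ID="3"/>
                {dangling}
              </Track>
            </AllTracks>
          </Model>
          {calib}
        </TrackMate>
        """
    )


class TestTrackmateXml:
    def test_counts_preserved(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(_trackmate_xml())
        g = track_io.read_trackmate_xml(p)
        assert g.n_spots == 3 and g.n_edges == 2

    def test_pixel_calibration_applied(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(_trackmate_xml(spatialunits="pixel", pixelwidth=0.1625))
        g = track_io.read_trackmate_xml(p)
        # spot 1 at (2.0, 4.0) px -> (0.325, 0.65) um
        assert g.spots[1].position == pytest.approx((2.0 * 0.1625, 4.0 * 0.1625))

    def test_pixel_without_calibration_errors(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(_trackmate_xml(spatialunits="pixel"))
        with pytest.raises(ValueError, match="calibration"):
            track_io.read_trackmate_xml(p)

    def test_missing_units_error(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(_trackmate_xml(spatialunits=""))
        with pytest.raises(ValueError, match="spatialunits"):
            track_io.read_trackmate_xml(p)

    def test_dangling_edge_names_spot(self, tmp_path):
        p = tmp_path / "t.xml"
        p.write_text(_trackmate_xml(bad_edge=True))
        with pytest.raises(ValueError, match="99"):
            track_io.read_trackmate_xml(p)


class TestSpotsCsv:
    def test_single_track_chain_without_edges(self):
        csv = io.StringIO(
            "TRACK_ID,SPOT_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n"
            + "\n".join(f"0,{i},{i},{i * 0.1},0.0,{i * 2.0}" for i in range(10))
        )
        g = track_io.read_spots_csv(csv)
        assert g.n_spots == 10 and g.n_edges == 9

    def test_interleaved_tracks_group_by_id(self):
        rows = []
        for f in range(5):
            rows.append(f"0,{f},{f},{f},0.0,{f * 2.0}")
            rows.append(f"1,{100 + f},{f},{f},5.0,{f * 2.0}")
        csv = io.StringIO(
            "TRACK_ID,SPOT_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n" + "\n".join(rows)
        )
        branches = track_io.split_branches(track_io.read_spots_csv(csv), min_spots=2)
        assert len(branches) == 2
        assert {b.track_id for b in branches} == {0, 1}

    def test_lowercase_alias_headers(self):
        csv = io.StringIO(
            "track_id,spot_id,frame,x,y,t\n0,0,0,0.0,0.0,0.0\n0,1,1,1.0,0.0,2.0"
        )
        g = track_io.read_spots_csv(csv)
        assert g.n_spots == 2

    def test_duplicate_frame_without_edges_errors(self):
        csv = io.StringIO(
            "TRACK_ID,SPOT_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n"
            "0,0,0,0,0,0\n0,1,0,1,0,0\n"
        )
        with pytest.raises(ValueError, match="duplicate frame"):
            track_io.read_spots_csv(csv)

    def test_non_numeric_coordinate_reports_row(self):
        csv = io.StringIO(
            "TRACK_ID,SPOT_ID,FRAME,POSITION_X,POSITION_Y,POSITION_T\n"
            "0,0,0,0,0,0\n0,1,1,oops,0,2\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            track_io.read_spots_csv(csv)


class TestSplitBranches:
    def _chain(self, n, track_id=0, start_id=0):
        spots = {
            start_id + i: track_io.Spot(
                spot_id=start_id + i, track_id=track_id, frame=i, t=2.0 * i,
                position=(float(i), 0.0),
            )
            for i in range(n)
        }
        edges = [(start_id + i, start_id + i + 1) for i in range(n - 1)]
        return spots, edges

    def test_linear_track_single_branch(self):
        spots, edges = self._chain(20)
        branches = track_io.split_branches(track_io.TrackGraph(spots, edges))
        assert len(branches) == 1 and branches[0].n_spots == 20

    def test_split_node_yields_parent_and_two_children(self):
        # frames 0..4 linear, spot 4 links to two successors continuing to frame 9
        spots, edges = self._chain(5)
        for child_start in (100, 200):
            for k in range(5):
                spots[child_start + k] = track_io.Spot(
                    spot_id=child_start + k, track_id=0, frame=5 + k, t=2.0 * (5 + k),
                    position=(float(5 + k), float(child_start) / 100),
                )
            edges.append((4, child_start))
            edges.extend((child_start + k, child_start + k + 1) for k in range(4))
        branches = track_io.split_branches(track_io.TrackGraph(spots, edges), min_spots=2)
        assert len(branches) == 3
        sizes = sorted(b.n_spots for b in branches)
        assert sizes == [5, 5, 5]
        # junction spot (id 4) belongs to the parent only
        owners = [b for b in branches if any(s.spot_id == 4 for s in b.spots)]
        assert len(owners) == 1
        assert owners[0].spots[0].frame == 0

    def test_min_spots_filter_reports_discards(self):
        spots, edges = self._chain(3)
        res = track_io.split_branches(track_io.TrackGraph(spots, edges), min_spots=5)
        assert len(res) == 0 and res.n_discarded == 1

    def test_cycle_detected(self):
        spots, edges = self._chain(4)
        edges.append((3, 0))
        with pytest.raises(ValueError, match="cyclic"):
            track_io.split_branches(track_io.TrackGraph(spots, edges), min_spots=2)

    def test_spot_conservation_across_split(self):
        spots, edges = self._chain(6)
        for k in range(3):
            spots[50 + k] = track_io.Spot(
                spot_id=50 + k, track_id=0, frame=3 + k, t=2.0 * (3 + k), position=(0.0, float(k))
            )
        edges.append((2, 50))
        edges.extend([(50, 51), (51, 52)])
        branches = track_io.split_branches(track_io.TrackGraph(spots, edges), min_spots=2)
        seen = [s.spot_id for b in branches for s in b.spots]
        assert len(seen) == len(set(seen)) == len(spots)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False), st.floats(-100, 100, allow_nan=False)
        ),
        min_size=2,
        max_size=30,
    )
)
def test_path_length_dominates_net_displacement(points):
    from tests.conftest import make_branch

    b = make_branch(points)
    assert b.path_length >= np.linalg.norm(b.net_displacement) - 1e-9


def test_simulated_tracks_roundtrip_to_micrometre_precision(tmp_path):
    cfg = simulate.TrackSimConfig(
        n_branches_per_class={"stationary": 3, "anterograde": 3, "retrograde": 2}, seed=7
    )
    spots, edges, truth = simulate.simulate_tracks(cfg)
    track_io.write_spots_csv(spots, edges, tmp_path / "s.csv", tmp_path / "e.csv")
    g = track_io.read_spots_csv(tmp_path / "s.csv", tmp_path / "e.csv")
    branches = track_io.split_branches(g)
    assert len(branches) == len(truth)
    by_track = {b.track_id: b for b in branches}
    for (tid, sid, frame, x, y, t) in spots.itertuples(index=False):
        spot = next(s for s in by_track[tid].spots if s.spot_id == sid)
        assert abs(spot.position[0] - x) < 1e-6 and abs(spot.position[1] - y) < 1e-6
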