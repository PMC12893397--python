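"""Simulate one control and one doxorubicin-treated recording.

Generates the two default synthetic scenes (organoid plus surrounding 2D
cells, 15 s at 50 frames/s), and writes the trace tables, ROI lists and
ground truth under results/scenes/.  Downstream scripts regenerate the
same scenes from the same seeds, so this step mainly materializes the
data for inspection.
"""

from pathlib import Path

from orgwave.io import write_roi_table, write_trace_table
from orgwave.presets import PRESETS
from orgwave.synthetic import generate_scene

SCENE_SEEDS = {"control": 2024, "dox": 2025}
OUT = Path(__file__).resolve().parent.parent / "results" / "scenes"


def main() -> None:
    for group, seed in SCENE_SEEDS.items():
        scene = generate_scene(PRESETS[group], seed=seed)
        outdir = OUT / group
        outdir.mkdir(parents=True, exist_ok=True)
        write_trace_table(scene.traces, outdir / "traces.csv")
        write_roi_table(scene.rois, outdir / "rois.csv")
        scene.ground_truth.to_csv(outdir / "ground_truth.csv", index=False,
                                  float_format="%.10g")
        n = len(scene.ground_truth) - 1
        abn = (scene.ground_truth["abnormality"] != "normal").mean()
        print(f"{group}: {n} surrounding cells, "
              f"{abn:.0%} abnormal, wrote {outdir}")


if __name__ == "__main__":
    main()
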