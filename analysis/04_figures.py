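#!/usr/bin/env python
"""Figures from the per-run CSVs: axial profiles with probe markers.

Reads the outputs of 02_steady_grid.py / 03_pulsatile_case.py style runs
(a directory of per-scenario folders) and renders, per scenario, the
sectional average velocity, average pressure, wall shear stress and wall
load along z with the probe stations marked.  PNGs go to
results/figures/.
"""
import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from stenoflow.geometry import probe_locations


def plot_run(run_dir: Path, outdir: Path) -> None:
    sections = run_dir / "sections.csv"
    if not sections.exists():
        return
    sec = pd.read_csv(sections)
    lo = pd.read_csv(run_dir / "wall_lower.csv")
    up = pd.read_csv(run_dir / "wall_upper.csv")
    fig, axes = plt.subplots(4, 1, figsize=(7, 10), sharex=True)
    z_mm = sec.z * 1e3
    axes[0].plot(z_mm, sec.mean_vmag, label="mean |V|")
    axes[0].plot(z_mm, sec.max_vmag, "--", label="peak |V|")
    axes[0].set_ylabel("velocity (m/s)")
    axes[1].plot(z_mm, sec.mean_p)
    axes[1].set_ylabel("mean p (Pa)")
    axes[2].plot(z_mm, lo.wss, label="lower")
    axes[2].plot(z_mm, up.wss, label="upper")
    axes[2].axhline(0.0, color="k", lw=0.5)
    axes[2].set_ylabel("WSS (Pa)")
    axes[3].plot(z_mm, lo.traction, label="lower")
    axes[3].plot(z_mm, up.traction, label="upper")
    axes[3].set_ylabel("wall load (Pa)")
    axes[3].set_xlabel("z (mm)")
    # probe markers from the scenario geometry encoded in the label
    try:
        parts = run_dir.name.split("_")
        model = int(parts[0][1:])
        s = float(parts[1][1:])
        from stenoflow.geometry import StenosisSpec, VesselSpec

        probes = probe_locations(StenosisSpec(model=model, s=s), VesselSpec())
        for ax in axes:
            for name, z in probes.items():
                ax.axvline(z * 1e3, color="gray", lw=0.4)
            ymax = axes[0].get_ylim()[1]
        for name, z in probes.items():
            axes[0].text(z * 1e3, ymax, name, fontsize=7, ha="center", va="bottom")
    except (ValueError, IndexError):
        pass
    axes[0].legend(fontsize=8)
    axes[2].legend(fontsize=8)
    fig.suptitle(run_dir.name)
    fig.tight_layout()
    out = outdir / f"{run_dir.name}.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    print(f"wrote {out}")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--runs", default="results/runs")
    ap.add_argument("--out", default="results/figures")
    args = ap.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    for run_dir in sorted(Path(args.runs).iterdir()):
        if run_dir.is_dir():
            plot_run(run_dir, outdir)


if __name__ == "__main__":
    main()
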