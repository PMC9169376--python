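"""Optional: run the full validation protocol on a recorded dataset.

Point this at a locally downloaded recording (CSV or XLSX with columns
magnitude/label and optionally t_ms, labels 0=Idle, 1=Stone, 2=Tissue) to
evaluate the pipeline on real data instead of the simulator.  The script
is a no-op if no path is given.

    python examples/07_real_recording_eval.py path/to/recording.xlsx
"""

import sys

import lithowarn as lw

if len(sys.argv) < 2:
    print(__doc__)
    sys.exit(0)

rec = lw.read_recording(sys.argv[1])
segments = lw.segment_recording(rec)
print(f"{len(rec)} samples -> {len(segments)} pure-label 500 ms windows")

cfg = lw.ValidationConfig(
    m=20, n_reps=20, k=10, seed=0,
    wavelets=("haar", "db2", "db4", "rbio2.4", "dmey"),
)
for name, report in lw.sweep_wavelets(segments, cfg).items():
    print(f"{name:9} mean_acc={report.mean_accuracy:.3f} "
          f"std={report.std_accuracy_folds:.3f} "
          f"minAUC={min(s.auc_mean for s in report.roc.values()):.3f}")
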