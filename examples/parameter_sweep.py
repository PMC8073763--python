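"""Classifier parameter sweep over the (σ, ρ) grid.

σ (percent of channels that must agree) and ρ (percent tolerance around
the median max-PLV position) are scanned 10–100% in steps of 10, ρ-major,
accumulating confusion counts over a small synthetic benchmark.
"""

from envsync.classify import sweep
from envsync.pipeline import PipelineConfig, process_record
from envsync.synth import benchmark_configs, generate_record

configs = benchmark_configs(
    seed=2, n_records=4, n_with_seizure=2,
    duration_s=600.0, n_channels=6, seizure_len_s=90.0,
)
cfg = PipelineConfig()
prepared = []
for c in configs:
    record, anns = generate_record(c)
    prepared.append((record.record_id, process_record(record, cfg), anns))

grid = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
rows = sweep(prepared, sigma_grid=grid, rho_grid=grid, sigma_mode="percent")

print("rho sigma  TP FP TN FN  sens  spec   acc")
for r in rows:
    if r["rho"] in (10, 50) and r["sigma"] in (10, 50, 90):
        print(
            f"{r['rho']:>3.0f} {r['sigma']:>5.0f}  {r['TP']:>2} {r['FP']:>2} "
            f"{r['TN']:>2} {r['FN']:>2}  {r['sensitivity']:.2f}  "
            f"{r['specificity']:.2f}  {r['accuracy']:.2f}"
        )
print(f"... {len(rows)} grid points total")
print()
print("Low sigma detects everything (FPs included); high sigma with a tight rho")
print("demands many channels agreeing in time, trading sensitivity for specificity.")
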