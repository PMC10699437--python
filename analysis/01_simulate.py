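"""Generate the synthetic provincial world every later step analyses.

Writes a 31-unit, four-zone, nine-indicator, 12-year panel with region
effects (west > northeast > central > east), an upward trend and moderate
spatial autocorrelation to results/analysis/inputs/.
"""

from pathlib import Path

from hra.synth import SyntheticConfig, write_bundle

OUT = Path("results/analysis/inputs")
SEED = 42


def main() -> None:
    cfg = SyntheticConfig()
    paths = write_bundle(cfg, OUT, seed=SEED)
    print(f"synthetic world written to {OUT} (seed {SEED}):")
    for k, p in paths.items():
        print(f"  {k:8s} {p}")
    print("shape: 31 units x 12 years x 9 indicators, zones (3, 10, 6, 12), "
          f"rho = {cfg.rho}, trend = {cfg.trend}/yr, noise sd = {cfg.noise_sd}")


if __name__ == "__main__":
    main()
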