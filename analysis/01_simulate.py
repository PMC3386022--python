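"""Generate the synthetic treatment-instance compendium used by the analysis.

Writes the full bundle (expression matrix, instance metadata, bioactivity
records, interaction network, probeset-gene map, pathway collection,
ground truth) as plain-text files under scratch/bundle/ and prints a
summary.  Every later analysis step regenerates the same bundle in memory
from the seed, so this materialisation exists for inspection and for
driving the command-line interface on real files.
"""

import sys
from pathlib import Path

from sigmin import SimConfig, generate
from sigmin.synthetic_data import write_bundle

SEED = 7
OUT = Path("scratch/bundle")


def main() -> None:
    cfg = SimConfig(seed=SEED)
    bundle = generate(cfg)
    write_bundle(bundle, OUT)
    m = bundle.expression
    print(f"bundle written to {OUT}/ (seed {SEED})")
    print(f"  {m.n_instances} treatment instances x {m.n_probesets} probesets, "
          f"{cfg.n_batches} batches")
    print(f"  {len(bundle.activities)} bioactivity records over "
          f"{cfg.n_compounds} compounds and {cfg.n_targets} targets")
    print(f"  {len(bundle.network.edges)} network edges, "
          f"{len(bundle.network.regulators())} expression-mode regulators")
    print(f"  {len(bundle.collection)} pathway sets "
          f"(planted: {bundle.truth.planted_set_name})")


if __name__ == "__main__":
    sys.exit(main())
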