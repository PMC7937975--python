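"""End-to-end pipeline run from a single config file.

Writes synthetic inputs, runs every stage (expression screen, SNP
characterization, paralog comparison) and renders the combined Markdown
report.  Identical config + seed gives byte-identical outputs.
"""

import tempfile
from pathlib import Path

from petalpath import run_pipeline

CONFIG = """\
[output]
dir = {out}
seed = 42
stages = simulate,expression,snps,paralogs,report

[simulate]
n_genes = 100
library_size_range = 50000,100000
"""

workdir = Path(tempfile.mkdtemp(prefix="petalpath_demo_"))
cfg_path = workdir / "demo.ini"
cfg_path.write_text(CONFIG.format(out=workdir / "out"))

report = run_pipeline(cfg_path)
for stage, info in report["stages"].items():
    print(f"{stage}: {info}")
print()
print((workdir / "out" / "report.md").read_text())
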