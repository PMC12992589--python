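"""Deterministic synthetic fixtures with ground-truth answer keys.

Every generator returns a :class:`FixtureBundle` holding in-memory models,
cross-reference/policy tables, and a ground-truth key that downstream tests
consume instead of recomputing expectations with the code under test.
Regenerating a bundle with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from ..core import MetabolicModel

__all__ = [
    "FixtureBundle",
    "make_core_energy_model",
    "make_mapping_fixture",
    "make_ump_fixture",
    "make_template_pair",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Fraction):
        return float(obj)
    return obj


@dataclass
class FixtureBundle:
    """Models, tables, specs and the answer key of one synthetic scenario."""

    name: str
    seed: int = 0
    models: dict[str, MetabolicModel] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    specs: dict[str, dict] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit SBML models, TSV tables, JSON specs/answer key and a manifest."""
        from ..io import write_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, model in sorted(self.models.items()):
            path = outdir / f"{name}.xml"
            write_model(model, path)
            written.append(path)
        for name, table in sorted(self.tables.items()):
            path = outdir / f"{name}.tsv"
            table.to_csv(path, sep="\t", index=False)
            written.append(path)
        for name, spec in sorted(self.specs.items()):
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(_jsonable(spec), indent=1, sort_keys=True) + "\n")
            written.append(path)
        key_path = outdir / "ground_truth.json"
        key_path.write_text(
            json.dumps(_jsonable(self.ground_truth), indent=1, sort_keys=True) + "\n"
        )
        written.append(key_path)
        manifest = {
            "fixture": self.name,
            "seed": self.seed,
            "files": [p.name for p in written],
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        written.append(manifest_path)
        return written


from .core_energy import make_core_energy_model  # noqa: E402
from .mapping import make_mapping_fixture  # noqa: E402
from .template_pair import make_template_pair  # noqa: E402
from .ump import make_ump_fixture  # noqa: E402
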