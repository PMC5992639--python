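"""Report writers and run manifests.

Every tabular output is CSV-style text with explicit units in the column
headers (AUD, QALY, persons) and a leading comment line referencing the
manifest of the run that produced it, so results stay traceable to the exact
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .parameters import ModelConfig, config_to_dict


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one model run: config checksum, seed, settings, version."""

    config_sha256: str
    seed: int
    settings: dict
    version: str
    timestamp: str

    @property
    def short_id(self) -> str:
        return self.config_sha256[:12]

    def to_dict(self) -> dict:
        return {
            "config_sha256": self.config_sha256,
            "seed": self.seed,
            "settings": self.settings,
            "version": self.version,
            "timestamp": self.timestamp,
        }


def make_manifest(config: ModelConfig, seed: int | None = None) -> RunManifest:
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    from .parameters import _settings_to_dict  # avoid a public re-export

    return RunManifest(
        config_sha256=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=config.settings.rng_seed if seed is None else seed,
        settings=_settings_to_dict(config.settings),
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )


def write_manifest(manifest: RunManifest, outdir: str | Path) -> Path:
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return path


def write_table(
    df: pd.DataFrame, path: str | Path, manifest: RunManifest
) -> Path:
    """Write a DataFrame as CSV with a manifest-reference comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest.short_id} (manifest.json)\n")
        df.to_csv(fh, index=False)
    return path


__all__ = ["RunManifest", "make_manifest", "write_manifest", "write_table"]
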