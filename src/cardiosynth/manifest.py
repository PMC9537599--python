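"""Run manifests: enough metadata to replay any CLI run exactly."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path


def _library_versions() -> dict:
    import numpy
    import pandas
    import scipy
    import skimage
    from importlib.metadata import version as _v
    return {"python": platform.python_version(),
            "numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__, "scikit-image": skimage.__version__,
            "cardiosynth": _v("cardiosynth")}


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)      # path -> sha256
    outputs: list = field(default_factory=list)
    versions: dict = field(default_factory=_library_versions)
    timestamp: str = field(default_factory=lambda: datetime.now(
        timezone.utc).isoformat())

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)
        return path
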