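"""Run metadata: version, configuration hash, seed echoing.

Every output table carries a comment header identifying the tool version,
a hash of the effective configuration, and the seed, so a result file can
always be traced back to the exact invocation that produced it.  Output
paths are excluded from the hash — where a result is written must not
change what it is.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping

from . import __version__

#: parameter names that never enter the configuration hash
_EXCLUDED_KEYS = frozenset({"out", "out_dir", "output", "path"})


def config_hash(params: Mapping[str, object]) -> str:
    """Deterministic short hash of a configuration mapping.

    Keys are sorted, output-path keys are dropped, and values are
    serialised to canonical JSON before hashing.
    """
    clean = {k: params[k] for k in sorted(params) if k not in _EXCLUDED_KEYS}
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(command: str, params: Mapping[str, object]) -> list[str]:
    """Comment lines to prepend to an output TSV."""
    lines = [
        f"# orabench v{__version__}",
        f"# command: {command}",
        f"# config_hash: {config_hash(params)}",
    ]
    if "seed" in params and params["seed"] is not None:
        lines.append(f"# seed: {params['seed']}")
    return lines


def write_tsv(frame, path, command: str, params: Mapping[str, object]) -> None:
    """Write a DataFrame as TSV with the provenance comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance_lines(command, params):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)
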