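"""Reader/writer for the tpsDig dialect of the TPS landmark file format.

A specimen block looks like::

    LM=60
    12.5 103.0
    ...            (60 whitespace-separated "x y" lines)
    ID=lig_001
    SCALE=0.0016

The reader tolerates CRLF line endings, trailing blank lines and lower-case
keywords; the writer emits LF.  Landmark ordinals are 1-based on disk
(matching the digitising convention) and 0-based in memory.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .morpho import LandmarkConfiguration


class TpsParseError(ValueError):
    pass


def read_tps(path, group: str = "", groups: Optional[dict] = None
             ) -> list[LandmarkConfiguration]:
    """Read all specimen blocks from a TPS landmark file.

    ``groups`` optionally maps specimen IDs to group labels; otherwise all
    specimens get ``group``.
    """
    configs: list[LandmarkConfiguration] = []
    lm_expect: Optional[int] = None
    points: list[list[float]] = []
    spec_id: Optional[str] = None
    scale: Optional[float] = None

    def flush(line_no: int) -> None:
        nonlocal lm_expect, points, spec_id, scale
        if lm_expect is None:
            return
        if len(points) != lm_expect:
            raise TpsParseError(
                f"line {line_no}: specimen {spec_id or '?'} has "
                f"{len(points)} landmarks, header said LM={lm_expect}"
            )
        sid = spec_id if spec_id is not None else str(len(configs))
        g = (groups or {}).get(sid, group)
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid, group=g,
                points=np.array(points), scale=scale,
            )
        )
        lm_expect, points, spec_id, scale = None, [], None, None

    line_no = 0
    with open(str(path)) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                try:
                    lm_expect = int(line[3:])
                except ValueError as exc:
                    raise TpsParseError(
                        f"line {line_no}: bad landmark count {line!r}"
                    ) from exc
            elif upper.startswith("ID="):
                spec_id = line[3:].strip()
            elif upper.startswith("SCALE="):
                scale = float(line[6:])
            elif upper.startswith(("IMAGE=", "COMMENT=")):
                continue
            else:
                parts = line.split()
                if lm_expect is None or len(parts) != 2:
                    raise TpsParseError(
                        f"line {line_no}: unexpected content {line!r}"
                    )
                try:
                    points.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise TpsParseError(
                        f"line {line_no}: bad coordinates {line!r}"
                    ) from exc
        flush(line_no + 1)
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write specimen blocks in the tpsDig dialect (LF line endings)."""
    with open(str(path), "w", newline="\n") as fh:
        for c in configs:
            fh.write(f"LM={len(c.points)}\n")
            for x, y in c.points:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={c.specimen_id}\n")
            if c.scale is not None:
                fh.write(f"SCALE={c.scale:.10g}\n")
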