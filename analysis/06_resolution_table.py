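"""USAF-1951 resolution arithmetic and field-of-view bookkeeping.

Prints the group/element table around the system's operating range and the
two resolved readings (full field: group 1 element 3; zoomed field: group 2
element 6), plus the field-of-view areas. Writes results/resolution.csv.
"""

from pathlib import Path

from mesofluor.optres import (
    FieldOfView,
    ResolutionSpec,
    resolution_table,
    round_display,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = resolution_table(range(-1, 4))
    df.to_csv(OUT / "resolution.csv", index=False)
    for g, e, fov in ((1, 3, (5.1, 5.1)), ((2), 6, (3.2, 3.2))):
        spec = ResolutionSpec.from_group_element(g, e)
        area = FieldOfView.from_dimensions(*fov)
        print(
            f"group {g} element {e}: {round_display(spec.frequency):.2f} lp/mm, "
            f"line width {round_display(spec.line_width):.2f} μm "
            f"(FOV {fov[0]} × {fov[1]} cm = {round_display(area.area_cm2):.2f} cm²)"
        )
    print(f"wrote {OUT / 'resolution.csv'}")


if __name__ == "__main__":
    main()
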