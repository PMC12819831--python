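"""Deterministic sentence template bank for the synthetic audit generator.

Eighteen statement categories, each with at least three slot-filled
templates.  Slots use ``{option a|option b}`` syntax; a realization picks
one option per slot.  Templates are plain strings (no generative model) and
each category keeps a distinctive core vocabulary so that a lexical
embedding backend can separate categories without any model download.

Category order is stable and is the category id used throughout the
package.  ``CATEGORY_BLOCKS`` groups the categories into the four
orientation blocks used by the default synthetic study design.
"""

from __future__ import annotations

import re

from .errors import ConfigError

# (category name, templates).  Every template carries >=3 independent slots
# so each yields dozens of distinct realizations; backbone nouns stay fixed
# per category so the lexical backend separates categories.
TEMPLATE_BANK: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "outdoor_activity_accessibility",
        (
            "The grounds are {well maintained|tidy and clean|free of litter} and the outdoor activity plaza is {open|spacious|generous}, supporting {strolling|morning exercise|group gymnastics} on the grounds",
            "The outdoor plaza and surrounding grounds are {clean|orderly|well kept}, with {intact|functional|serviceable} amenities for group activities and {gentle exercise|daily movement|communal events}",
            "An {open|expansive|broad} outdoor plaza on the grounds is {well kept|free of clutter|carefully maintained} and hosts group activities in {most|all|fair} weather",
            "The outdoor grounds offer a {level|smooth|even} activity plaza where residents hold group activities and {exercise|gatherings|games}, kept {tidy|clean|orderly} throughout",
        ),
    ),
    (
        "interior_color_decoration",
        (
            "The room decor uses a {fresh|warm|gentle} color palette with {framed|hanging|mounted} artwork, and furnishings are kept {orderly|neat|uncluttered}",
            "Interior decor features a {soft|low-saturation|pastel} color palette, artwork on the walls and a {homelike|welcoming|calm} atmosphere",
            "Walls carry {calligraphy|painted|photographic} artwork, the color palette of the decor is {warm|muted|subdued} and {tasteful|restrained|harmonious}",
            "Wood finishes and {matte|low-gloss|satin} surfaces give the decor a {calm|quiet|soothing} low-saturation color palette, with artwork {placed|arranged|hung} sparingly",
        ),
    ),
    (
        "open_plan_living_area",
        (
            "The living area has an open-plan layout with a {wide|broad|unobstructed} visual field, furnished with a lounge of {sofas|settees|armchairs} for group leisure",
            "An open-plan lounge offers {sofas|soft seating|upholstered chairs} and {low|side|coffee} tables, suited to {group recreation|shared leisure|social play} and leisure for residents",
            "The communal lounge is open-plan and {spacious|airy|light-filled}, arranged for {games|cards|mahjong} and group leisure in a {relaxed|informal|flexible} layout",
            "Open-plan leisure space in the living area holds {game tables|mahjong tables|card tables} and a sofa lounge, giving residents {ample|generous|plentiful} room",
        ),
    ),
    (
        "bathroom_configuration",
        (
            "The bathroom has {light-colored|small square|glazed} tiles, a toilet with grab bars on {both sides|either side|each flank} and a shower area with a {folding seat|shower chair|bath stool}",
            "The bathroom is fitted with a {countertop|wall-hung|pedestal} sink, a mirror, grab bars beside the toilet and a {handheld|wall-mounted|adjustable} shower head",
            "Bathroom fixtures include grab bars, a {fold-down|portable|fixed} shower seat and {non-slip|textured|matte} tiling in the {wet|washing|shower} zone",
            "A {compact|small|space-efficient} bathroom provides a toilet with {twin|paired|flanking} grab bars and a shower area with a {drainage slope|floor drain|level threshold}",
        ),
    ),
    (
        "site_greenery",
        (
            "The greenery features {dense|layered|abundant} vegetation, with trees and shrubs {well maintained|pruned|carefully tended} and coverage {high|extensive|thriving}",
            "Vegetation of {mixed|varied|native} trees and shrubs shows {healthy|vigorous|robust} growth, and the greenery includes {lawns|flower beds|planting strips} in good condition",
            "Site greenery is {rich|abundant|generous}, with shrubs, {mature|shade|flowering} trees and vegetation in {healthy|vigorous|flourishing} condition",
            "Plantings of {evergreen|flowering|broadleaf} shrubs and trees give {substantial|extensive|high} vegetation coverage, and the greenery shows {seasonal|varied|diverse} species",
        ),
    ),
    (
        "care_bed_arrangement",
        (
            "The bedroom is furnished with a {light wood-tone|height-adjustable|rail-equipped} nursing bed, a bedside cabinet and {complete|fresh|neatly folded} bedding",
            "A nursing bed with {side rails|safety rails|lifting handles} stands by the wall, with a bedside cabinet and bedding {arranged|folded|laid out} neatly",
            "The care room holds a nursing bed with its headboard {against|along|to} the wall, complete bedding and a bedside {cabinet|table|unit} for personal items",
            "Each resident room provides a nursing bed, {tidy|complete|seasonal} bedding and a bedside cabinet {for personal items|within reach|beside the pillow}",
        ),
    ),
    (
        "natural_lighting_windows",
        (
            "The interior features {large|generous|full-height} windows with {venetian blinds|curtains|roller shades}, letting {ample|abundant|plentiful} natural daylight in",
            "{Floor-to-ceiling|Broad|Paired} windows bring in natural daylight, with {curtains|blinds|shades} to {adjust|moderate|soften} the light",
            "Generous window area gives the room {bright|even|steady} daylight, and windows carry {shading|blackout|adjustable} curtains against glare",
            "Daylight enters through {south-facing|wide|unobstructed} windows, whose sills are kept {clear|uncluttered|low} to preserve the natural light",
        ),
    ),
    (
        "lighting_system",
        (
            "Ceiling luminaires, recessed downlights and {wall-mounted|indirect|cove} fittings provide {uniform|layered|even} illumination at a {neutral|warm|comfortable} color temperature",
            "The illumination scheme combines {pendant|ceiling|track} luminaires with recessed downlights for {sufficient|uniform|glare-free} lighting levels",
            "Linear luminaire strips along the ceiling and {recessed|surface-mounted|suspended} downlights improve illumination {uniformity|coverage|consistency}",
            "Artificial illumination is {ample|evenly distributed|well layered}, using downlights and indirect luminaires with a {neutral|warm-white|soft} tone",
        ),
    ),
    (
        "surface_paving",
        (
            "The ground surface is paved with {asphalt|concrete|interlocking block} paving, which is {even|level|smooth} and {easy|safe|comfortable} to traverse",
            "The paving is {level|smooth|flat} and slip-resistant, with the {asphalt|brick|stone} surface in {good|sound|fresh} repair",
            "Paving in a {grid|modular|unit} pattern with {edge bands|border strips|contrast edging} keeps the ground surface {even|stable|firm} underfoot",
            "The paved surface is {crack-free|well maintained|recently resurfaced}, an {even|level|continuous} paving plane for {frames|trolleys|carts}",
        ),
    ),
    (
        "wayfinding_signage",
        (
            "Informational signage and {display|notice|message} boards are affixed to the walls, supporting wayfinding along the {corridor|hallway|route}",
            "Directional signage with {high-contrast|illuminated|oversized} lettering marks each zone for {easy|quick|reliable} wayfinding",
            "Wall-mounted display boards and {room-number|floor-map|pictogram} signage provide {clear|legible|consistent} wayfinding cues",
            "Wayfinding signage is {consistent|legible|color-coded}, with {arrows|labels|symbols} at {decision points|junctions|door heads}",
        ),
    ),
    (
        "building_facade",
        (
            "The main exterior facade of the building is in {light|neutral|pale} tones, with {simple|restrained|plain} cladding on a {multi-story|mid-rise|stepped} elevation",
            "The building facade uses {tile|render|panel} cladding in {light|soft|warm} colors and a {restrained|simple|orderly} elevation",
            "A multi-story facade with {regular|orderly|rhythmic} window bays presents a {clean|tidy|composed} exterior elevation",
            "Exterior facade elevations are {freshly painted|well kept|recently renovated}, with {light-toned|pale|cream} cladding and {modest|simple|measured} articulation",
        ),
    ),
    (
        "ventilation_air",
        (
            "Ventilation is achieved through {operable|openable|tilting} external openings together with {air conditioning|mechanical ventilation|ceiling fans} for air exchange",
            "{Split|Wall-mounted|Cassette} air-conditioning units and {exhaust fans|transfer grilles|vent louvres} provide ventilation and {temperature|humidity|climate} control",
            "The room relies on {cross-ventilation|stack ventilation|natural airflow} supplemented by air conditioning to keep the air {fresh|circulating|comfortable}",
            "{Smoke-extraction|Air-purification|Fresh-air} ventilation equipment is installed alongside air conditioning to {ensure|maintain|support} air quality",
        ),
    ),
    (
        "spatial_scale_wheelchair",
        (
            "The space is {wide|broad|generously sized} with {generous|ample|full} clearance, and wheelchair circulation and turning are possible {throughout|everywhere|in every zone}",
            "Corridor width and door clearance accommodate wheelchair {passage|movement|transfers} without {obstruction|narrow points|pinch points}",
            "Circulation is {barrier-free|step-free|threshold-free}, with turning clearance for wheelchairs at {junctions|doorways|corners}",
            "Generous spatial scale leaves {maneuvering|turning|passing} clearance so wheelchairs can {pass two abreast|turn fully|move unassisted}",
        ),
    ),
    (
        "public_seating_reception",
        (
            "Sets of tables and chairs are arranged near the reception counter, forming a {social|conversational|group} layout in the {entry hall|lobby|foyer}",
            "A reception counter with tables and chairs nearby anchors the {lobby|entry hall|foyer}, with {shelving|a notice board|planters} alongside",
            "Grouped tables and chairs in the {lobby|hall|foyer} encourage {conversation|gathering|visiting}, with a {staffed|wooden|curved} reception desk at the entry",
            "The {lobby|foyer|hall} provides {clustered|facing|paired} tables and chairs and a reception counter for {visitors|families|guests}",
        ),
    ),
    (
        "entry_roadway",
        (
            "A vehicular lane with an {asphalt|sealed|smooth} driveway surface runs on one side of the approach, {bounded|separated|divided} from the footpath by a {kerb|barrier|planting strip}",
            "The driveway is separated from the footpath by a {kerb|painted boundary|guard rail}, keeping vehicular traffic and {pedestrians|walkers|residents} apart",
            "A vehicular drop-off lane on the driveway adjoins a {raised|marked|protected} footpath with a {clear|continuous|visible} boundary",
            "The site driveway provides {one-way|two-way|looped} vehicular access beside a {protected|separated|dedicated} footpath",
        ),
    ),
    (
        "entrance_structure",
        (
            "At the {corner|street front|main approach} an {arched|columned|framed} entrance gate with a wall opening is provided, with a {nameboard|lintel board|title board} above",
            "The main entrance gate features a {nameboard|brass plate|carved board} and {fencing|railings|boundary walls}, marking a {clearly legible|prominent|recognizable} threshold",
            "An entrance {canopy|portico|awning} and gate {piers|posts|columns} define the threshold into the facility",
            "The entrance gateway is {prominent|clearly marked|easily identified}, combining {fencing|railings|walls}, a nameboard and a {controlled|gated|monitored} opening",
        ),
    ),
    (
        "rehabilitation_equipment",
        (
            "The training room holds multiple sets of rehabilitation and exercise equipment, including {parallel bars|suspension trainers|pedal machines}, with a {wide|clear|broad} field of view",
            "Rehabilitation equipment such as {exercise bikes|pedal trainers|arm ergometers} and parallel bars is arranged in the training area with {open|clear|free} floor space",
            "A physiotherapy training zone provides {suspended|pulley|resistance} rehabilitation equipment and {therapy|treatment|rehabilitation} chairs for {daily|scheduled|routine} sessions",
            "Exercise and rehabilitation equipment stands in {rows|stations|bays}, leaving training floor area for {gait|balance|strength} work",
        ),
    ),
    (
        "shaded_outdoor_circulation",
        (
            "A shaded corridor with a {transparent|translucent|louvred} canopy runs along the garden, with {flowerbeds|planters|borders} alongside and benches for {rest|pausing|sitting}",
            "A pergola canopy covers the shaded link between buildings, offering {sun|rain|weather} protection and benches at {intervals|corners|regular spacings}",
            "Covered circulation under a {metal-framed|polycarbonate|timber} canopy provides a shaded route with benches at {seating nodes|rest points|pause points}",
            "Shaded routes under {overhead canopies|rain pavilions|trellises} allow outdoor movement in {all|any|variable} weather, with benches for residents and {visitors|caregivers|families}",
        ),
    ),
)

N_CATEGORIES = len(TEMPLATE_BANK)

CATEGORY_NAMES: tuple[str, ...] = tuple(name for name, _ in TEMPLATE_BANK)

#: Orientation blocks used by the default four-type study design:
#: interior comfort/safety, site layout & access, landscape/greenery,
#: rehabilitation function.
CATEGORY_BLOCKS: dict[str, tuple[str, ...]] = {
    "interior": (
        "interior_color_decoration",
        "bathroom_configuration",
        "care_bed_arrangement",
        "natural_lighting_windows",
        "lighting_system",
        "ventilation_air",
    ),
    "layout": (
        "surface_paving",
        "wayfinding_signage",
        "building_facade",
        "entry_roadway",
        "entrance_structure",
    ),
    "landscape": (
        "outdoor_activity_accessibility",
        "site_greenery",
        "shaded_outdoor_circulation",
    ),
    "rehabilitation": (
        "open_plan_living_area",
        "spatial_scale_wheelchair",
        "public_seating_reception",
        "rehabilitation_equipment",
    ),
}

_SLOT = re.compile(r"\{([^{}]*)\}")


def realize_template(template: str, rng) -> str:
    """Fill every ``{a|b}`` slot with one option chosen by ``rng``."""

    def _fill(match: re.Match) -> str:
        options = match.group(1).split("|")
        return options[rng.integers(len(options))]

    return _SLOT.sub(_fill, template)


def category_index(name: str) -> int:
    try:
        return CATEGORY_NAMES.index(name)
    except ValueError:
        raise ConfigError(f"unknown template category: {name!r}") from None
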