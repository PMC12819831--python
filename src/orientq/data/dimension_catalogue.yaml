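# Built-environment audit indicator catalogue for long-term-care facilities.
# Used to instruct an external image auditor (see corpus.render_audit_prompt).
dimensions:
  - group: indoor
    name: Daylighting and lighting conditions
    indicators: Window orientation and area; number and color temperature of luminaires; blackout or shading curtains.
  - group: indoor
    name: Ventilation and indoor air quality
    indicators: Operable doors and windows; mechanical ventilation or air-purification devices.
  - group: indoor
    name: Spatial layout and privacy
    indicators: Open-plan versus compartmentalized functional zones; corridor length; extent of visual exposure and sightlines.
  - group: indoor
    name: Safety and assistive features
    indicators: Bathroom grab bars; corridor lighting; handrail-wall luminance contrast; wayfinding signage; nurse-call buttons.
  - group: indoor
    name: Spatial capacity
    indicators: Overall spaciousness; wheelchair accessibility and maneuvering clearance.
  - group: indoor
    name: Comfortable and flexible furniture
    indicators: Relative placement of beds to windows and desks; social seating configurations.
  - group: indoor
    name: Environmental aesthetics and art elements
    indicators: Decorative objects and style; indoor plants; proportion of timber; material reflectance; color palette and saturation.
  - group: outdoor
    name: Greening and natural elements
    indicators: Vegetation coverage; species richness and health; water features.
  - group: outdoor
    name: Accessible design and facilities
    indicators: Entrances and site boundaries; fencing; handrails; sidewalk and path width; outdoor furniture; color contrast.
  - group: outdoor
    name: Main-building design
    indicators: Facade articulation and complexity; architectural style; materials; color scheme; visual interest.
  - group: outdoor
    name: Entrance forecourt and seating
    indicators: Provision of seating in the entrance plaza; steps; landscape ornaments; scale and proportions.
  - group: outdoor
    name: Paths and surface conditions
    indicators: Walkway width; paving materials; diversity of route types.
  - group: outdoor
    name: Shade and shelter
    indicators: Shaded or rain pavilions; terraces; overhead canopies.
  - group: outdoor
    name: Visibility and night-time lighting
    indicators: Pedestrian-path and facade lighting provision.
  - group: outdoor
    name: Proximity and activity intensity
    indicators: Connectivity to commercial streets; openness; streetscape vibrancy; access to public services.
  - group: outdoor
    name: Environmental quality
    indicators: Cleanliness and maintenance; condition of facilities; orderliness.
  - group: outdoor
    name: Social opportunities
    indicators: Activity and interaction amenities; furniture for gathering; family-visit and group-activity facilities.
  - group: free
    name: Free dimension
    indicators: Any salient environmental attribute not covered above, such as cultural symbols, pet-friendly amenities, digital devices, or specialized activity rooms.
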