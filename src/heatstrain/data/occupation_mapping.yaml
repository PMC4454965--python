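# Occupation category -> weather exposure and exertion level.
# exposure: not_exposed | indoors | outdoors
# exertion: rest | minimal | moderate | heavy
# Edit a copy of this file and pass it via --mapping to reclassify.
office: {exposure: indoors, exertion: minimal}
sales_clerical: {exposure: indoors, exertion: minimal}
education_health: {exposure: indoors, exertion: minimal}
manufacturing: {exposure: indoors, exertion: moderate}
hospitality: {exposure: indoors, exertion: moderate}
construction: {exposure: outdoors, exertion: heavy}
agriculture: {exposure: outdoors, exertion: heavy}
outdoor_trades: {exposure: outdoors, exertion: moderate}
transport: {exposure: outdoors, exertion: minimal}
home_duties: {exposure: indoors, exertion: rest}
student: {exposure: indoors, exertion: minimal}
not_in_labour_force: {exposure: not_exposed, exertion: rest}
child_indoor: {exposure: indoors, exertion: minimal}
outdoor_play: {exposure: outdoors, exertion: moderate}
retired_home: {exposure: indoors, exertion: rest}
light_activity_indoor: {exposure: indoors, exertion: minimal}
housework_moderate: {exposure: indoors, exertion: moderate}
gardening_outdoor: {exposure: outdoors, exertion: moderate}
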