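# Default synthetic crawl: a ~1 mm peristaltic crawler on an E = 28 kPa
# microcavity, imaged at x4 magnification and 120 camera FPS (60 maps/s).
# Values are the package defaults; each entry notes where its scale comes from.

n_protopodia: 6               # abdominal contact segments in the field of view
indenter_radius_um: 100.0     # effective Hertz sphere of one protopodium
# peak depths are reverse-engineered: with E = 28 kPa, a 10 um layer and
# R = 100 um, depths of 1000-1400 nm put the per-protopodium ground reaction
# forces in the observed 1-7 uN range (they land at ~1.3-2.6 uN)
peak_depths_nm: [1000.0, 1080.0, 1160.0, 1240.0, 1320.0, 1400.0]
spacing_um: 30.0              # centre-to-centre; leaves footprints disjoint after a step
step_length_um: 6.0           # forward displacement per wave

start_at_rest: true           # series opens with the animal settling onto the cavity
settle_time_s: 0.05

wave_start_s: 0.9             # leaves room for settling + the tripod lead
wave_duration_s: 1.2          # typical forward-wave duration (order of seconds)
n_waves: 1
wave_rest_s: 0.4
direction: forward
swing_fraction: 0.35          # swing period / wave duration
release_time_s: 0.25          # lift-off ramp after swing initiation
landing_rise_s: 0.30          # local depth ramp after contact onset

# sub-protopodial landing spread: posterior denticle rows strike first and the
# contact expands anteriorly (~50 ms per 3 um row -> ~0.25 s across a
# protopodium) and outward from the midline (~30 ms per 3 um)
ap_landing_delay_s: 0.05
ap_row_spacing_um: 3.0
ml_landing_delay_s: 0.03
ml_spacing_um: 3.0

# programmed anteroposterior row latencies for the landmark tracks:
# swing-initiation latency scales with wave duration (10% of it), the
# swing-termination latency is smaller and duration-independent in character
si_latency_fraction: 0.10
st_latency_fraction: 0.05

tripod_enabled: true
tripod_lead_s: 0.66           # tripod contact precedes A7 lift-off by 0.66 s
tripod_depth_nm: 500.0
tripod_radius_um: 10.0
tripod_offset_um: [15.0, 14.0]  # posterior of the terminal protopodium, bilateral
tripod_ramp_s: 0.2
timing_jitter_s: 0.0

droplet_enabled: false        # optional upward annulus from the carried water droplet
droplet_radius_um: 70.0
droplet_amplitude_nm: 60.0
droplet_width_um: 6.0

grf_area_law: null            # when set: [a2, a1, a0] nN vs um^2 quadratic
contact_threshold_nm: -20.0   # noise-margin contact definition for truth areas
substrate_E_pa: 28000.0

rest_thickness_nm: 10000.0    # static cavity length, within the 8-12 um build range
shape: [128, 224]             # rows (mediolateral) x cols (anteroposterior), pixels
pixel_size_um: 1.0
map_rate: 60.0                # displacement maps / s (camera runs at 2x)
intensity_noise: 0.0
displacement_jitter_nm: 0.0
seed: 0
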