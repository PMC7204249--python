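# Neutral note vocabulary for the synthetic generator, one token per line.
# Deliberately disjoint from data/ae_terms.txt so that every adverse-event
# token in generated text is attributable to the AE dictionary.
patient
seen
today
morning
evening
night
ward
room
calm
settled
cooperative
pleasant
quiet
talkative
alert
oriented
sleep
slept
well
poorly
appetite
meals
eaten
fluids
weight
observed
medication
given
taken
administered
refused
accepted
dose
tablet
depot
injection
prescribed
continued
unchanged
reviewed
review
plan
planned
assessment
status
mental
state
mood
affect
neutral
stable
improved
improving
baseline
thoughts
speech
normal
coherent
organised
contact
conversation
spoke
discussed
informed
family
mother
father
visit
visited
phone
called
staff
nurse
doctor
consultant
team
meeting
round
conference
leave
ground
walk
activity
attended
group
therapy
session
exercise
occupational
program
schedule
daily
routine
hygiene
dressed
shower
clothes
cleaned
tidy
breakfast
lunch
dinner
coffee
smoking
garden
reading
television
music
resting
rested
bed
awake
woke
asleep
checked
observation
fifteen
minutes
hourly
vitals
pulse
pressure
temperature
measured
recorded
noted
documented
chart
record
admission
admitted
discharge
planning
follow
outpatient
clinic
appointment
social
worker
contacted
housing
support
benefits
application
letter
written
signed
consent
agreed
request
requested
declined
denies
reports
states
expressed
feeling
feels
better
worse
same
cooperated
participated
engaged
withdrawn
isolative
interacting
peers
milieu
environment
safety
risk
low
moderate
none
denied
voices
concerns
concern
ongoing
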