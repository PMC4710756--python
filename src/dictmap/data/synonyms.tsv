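# Starter synonym/abbreviation list for element-name component matching.
# Two or more columns per line: term <tab> synonym [<tab> synonym ...]
# The map is applied symmetrically. Edit freely; an empty file is legal.
gender	sex
subject	participant	patient
dob	birthdate
bp	pressure
sys	systolic
dia	diastolic
hr	pulse
wt	weight
ht	height
edu	education
educ	education
occ	occupation
eth	ethnicity
lang	language
mem	memory
orient	orientation
att	attention
dep	depression
anx	anxiety
med	medication
hx	history
dx	diagnosis
assess	assessment
assmt	assessment
sev	severity
freq	frequency
dur	duration
tot	total
cnt	count
num	count
avg	average
min	minimum
max	maximum
visit	exam
score	rating
id	identifier
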