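"""Synthetic name-part and institution lexicon for the registry generator.

All entries are invented or generic Indian-style name parts assembled at
random; no list corresponds to real investigators. Keeping the lexicon
bundled (rather than sampling real rosters) keeps generated datasets
privacy-safe and byte-reproducible.
"""

GIVEN_NAMES = (
    "Anita", "Anil", "Arun", "Asha", "Amit", "Ajay", "Alok", "Aparna", "Arvind", "Bhavna",
    "Bharat", "Chetan", "Chitra", "Deepa", "Dinesh", "Divya", "Gaurav", "Geeta", "Girish",
    "Harish", "Hema", "Indira", "Jaya", "Jitendra", "Kavita", "Kiran", "Kamal", "Lakshmi",
    "Lalita", "Mahesh", "Manju", "Meena", "Mohan", "Mukesh", "Nandini", "Naresh", "Neha",
    "Nikhil", "Nisha", "Pankaj", "Pooja", "Prakash", "Pratap", "Priya", "Rajesh", "Rakesh",
    "Ramesh", "Ranjana", "Ravi", "Rekha", "Rohit", "Sanjay", "Sarita", "Savita", "Seema",
    "Shalini", "Shankar", "Sharad", "Shobha", "Sudha", "Sudhir", "Sunil", "Suresh", "Sushma",
    "Swati", "Tara", "Uday", "Uma", "Usha", "Vandana", "Varun", "Vidya", "Vijay", "Vikram",
    "Vinod", "Yogesh",
)

MIDDLE_NAMES = (
    "Kumar", "Kumari", "Chandra", "Prasad", "Devi", "Nath", "Lal", "Mohan", "Raj", "Ram",
    "Kant", "Narayan", "Prakash", "Shanker", "Babu",
)

SURNAMES = (
    "Sharma", "Verma", "Gupta", "Mehta", "Patel", "Reddy", "Iyer", "Nair", "Menon", "Rao",
    "Chopra", "Kapoor", "Malhotra", "Bhatia", "Saxena", "Srivastava", "Mishra", "Tripathi",
    "Dubey", "Pandey", "Joshi", "Desai", "Shah", "Kulkarni", "Deshpande", "Patil", "Naik",
    "Hegde", "Shetty", "Pillai", "Das", "Bose", "Sen", "Ghosh", "Mukherjee", "Banerjee",
    "Chatterjee", "Roy", "Dutta", "Sinha", "Jha", "Thakur", "Chauhan", "Rathore", "Solanki",
    "Yadav", "Chaudhary", "Agarwal", "Bansal", "Goel", "Jindal", "Singhal", "Khanna",
    "Ahuja", "Arora", "Batra", "Dhawan", "Grover", "Kohli", "Luthra", "Sodhi", "Tandon",
)

HONORIFIC_FORMS = ("Dr", "Dr.", "Prof", "Prof.", "Mr", "Mrs", "Ms", "Shri", "Smt")

CITIES = (
    "Akola", "Bellary", "Cuttack", "Dharwad", "Erode", "Guntur", "Hosur", "Imphal",
    "Jalgaon", "Karnal", "Latur", "Mandya", "Nellore", "Ongole", "Palghar", "Raichur",
    "Sangli", "Tumkur", "Udupi", "Vellore", "Warangal", "Yavatmal",
)

ORG_DESCRIPTORS = (
    "Sunrise", "Lotus", "Cavery", "Himalaya", "Pinnacle", "Meridian", "Harmony",
    "Evergreen", "Silverline", "Crescent", "Beacon", "Keystone",
)

ORG_TYPES = (
    "Institute of Medical Sciences", "Clinical Research Centre", "General Hospital",
    "Speciality Clinic", "Research Foundation", "Medical College", "Therapeutics Ltd",
    "Biosciences Pvt Ltd",
)

EMAIL_DOMAINS = ("example.org", "trialmail.in", "clinres.in", "medmail.org")
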