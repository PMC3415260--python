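"""Regenerates the bundled stand-in name lists.

Expands hand-written core lists of common given names and surnames with
diminutives, feminine/masculine spelling variants, common misspellings
(vowel dropped), and patronymic surname derivations, to reach >= 1000
entries per list. Output committed as plain text under
src/p2pwatch/resources/names/.
"""
from pathlib import Path

FEMALE_CORE = """
Mary Patricia Linda Barbara Elizabeth Jennifer Maria Susan Margaret Dorothy
Lisa Nancy Karen Betty Helen Sandra Donna Carol Ruth Sharon Michelle Laura
Sarah Kimberly Deborah Jessica Shirley Cynthia Angela Melissa Brenda Amy
Anna Rebecca Virginia Kathleen Pamela Martha Debra Amanda Stephanie Carolyn
Christine Marie Janet Catherine Frances Ann Joyce Diane Alice Julie Heather
Teresa Doris Gloria Evelyn Jean Cheryl Mildred Katherine Joan Ashley Judith
Rose Janice Kelly Nicole Judy Christina Kathy Theresa Beverly Denise Tammy
Irene Jane Lori Rachel Marilyn Andrea Kathryn Louise Sara Anne Jacqueline
Wanda Bonnie Julia Ruby Lois Tina Phyllis Norma Paula Diana Annie Lillian
Emily Robin Peggy Crystal Gladys Rita Dawn Connie Florence Tracy Edna
Tiffany Carmen Rosa Cindy Grace Wendy Victoria Edith Kim Sherry Sylvia
Josephine Thelma Shannon Sheila Ethel Ellen Elaine Marjorie Carrie Charlotte
Monica Esther Pauline Emma Juanita Anita Rhonda Hazel Amber Eva Debbie
April Leslie Clara Lucille Jamie Joanne Eleanor Valerie Danielle Megan
Alicia Suzanne Michele Gail Bertha Darlene Veronica Jill Erin Geraldine
Lauren Cathy Joann Lorraine Lynn Sally Regina Erica Beatrice Dolores
Bernice Audrey Yvonne Annette Samantha Marion Dana Stacy Ana Renee Ida
Vivian Roberta Holly Brittany Melanie Loretta Yolanda Jeanette Laurie
Katie Kristen Vanessa Alma Sue Elsie Beth Jeanne Vicki Carla Tara Rosemary
Eileen Terri Gertrude Lucy Tonya Ella Stacey Wilma Gina Kristin Jessie
Natalie Agnes Vera Willie Charlene Bessie Delores Melinda Pearl Arlene
Maureen Colleen Allison Tamara Joy Georgia Constance Lillie Claudia Jackie
Marcia Tanya Nellie Minnie Marlene Heidi Glenda Lydia Viola Courtney
Marian Stella Caroline Dora Jo Vickie Mattie Terry Maxine Irma Mabel
Marsha Myrtle Lena Christy Deanna Patsy Hilda Gwendolyn Jennie Nora
Margie Nina Cassandra Leah Penny Kay Priscilla Naomi Carole Brandy Olga
Billie Dianne Tracey Leona Jenny Felicia Sonia Miriam Velma Becky Bobbie
Violet Kristina Toni Misty Mae Shelly Daisy Ramona Sherri Erika Katrina
Claire Lindsey Lindsay Geneva Guadalupe Belinda Margarita Sheryl Cora
Faye Ada Natasha Sabrina Isabel Marguerite Hattie Harriet Molly Cecilia
Kristi Brandi Blanche Sandy Rosie Joanna Iris Eunice Angie Inez Lynda
Madeline Leila Zoe Chloe Sophia Isabella Olivia Mia Ava Abigail Hannah
Ella Avery Scarlett Grace Lily Aria Layla Nora Hazel Aurora Savannah
""".split()

MALE_CORE = """
James John Robert Michael William David Richard Charles Joseph Thomas
Christopher Daniel Paul Mark Donald George Kenneth Steven Edward Brian
Ronald Anthony Kevin Jason Matthew Gary Timothy Jose Larry Jeffrey Frank
Scott Eric Stephen Andrew Raymond Gregory Joshua Jerry Dennis Walter
Patrick Peter Harold Douglas Henry Carl Arthur Ryan Roger Joe Juan Jack
Albert Jonathan Justin Terry Gerald Keith Samuel Willie Ralph Lawrence
Nicholas Roy Benjamin Bruce Brandon Adam Harry Fred Wayne Billy Steve
Louis Jeremy Aaron Randy Howard Eugene Carlos Russell Bobby Victor Martin
Ernest Phillip Todd Jesse Craig Alan Shawn Clarence Sean Philip Chris
Johnny Earl Jimmy Antonio Danny Bryan Tony Luis Mike Stanley Leonard
Nathan Dale Manuel Rodney Curtis Norman Allen Marvin Vincent Glenn
Jeffery Travis Jeff Chad Jacob Lee Melvin Alfred Kyle Francis Bradley
Jesus Herbert Frederick Ray Joel Edwin Don Eddie Ricky Troy Randall
Barry Alexander Bernard Mario Leroy Francisco Marcus Micheal Theodore
Clifford Miguel Oscar Jay Jim Tom Calvin Alex Jon Ronnie Bill Lloyd
Tommy Leon Derek Warren Darrell Jerome Floyd Leo Alvin Tim Wesley
Gordon Dean Greg Jorge Dustin Pedro Derrick Dan Lewis Zachary Corey
Herman Maurice Vernon Roberto Clyde Glen Hector Shane Ricardo Sam
Rick Lester Brent Ramon Charlie Tyler Gilbert Gene Marc Reginald
Ruben Brett Angel Nathaniel Rafael Leslie Edgar Milton Raul Ben
Chester Cecil Duane Franklin Andre Elmer Brad Gabriel Ron Mitchell
Roland Arnold Harvey Jared Adrian Karl Cory Claude Erik Darryl Jamie
Neil Jessie Christian Javier Fernando Clinton Ted Mathew Tyrone Darren
Lonnie Lance Cody Julio Kelly Kurt Allan Nelson Guy Clayton Hugh Max
Dwayne Dwight Armando Felix Jimmie Everett Jordan Ian Wallace Ken Bob
Jaime Casey Alfredo Alberto Dave Ivan Johnnie Sidney Byron Julian Isaac
Morris Clifton Willard Daryl Ross Virgil Andy Marshall Salvador Perry
Kirk Sergio Marion Tracy Seth Kent Terrance Rene Eduardo Terrence Enrique
Freddie Wade Stuart Fredrick Arturo Alejandro Jackie Joey Nick Luther
Wendell Jeremiah Evan Julius Dana Donnie Otis Shannon Trevor Oliver
Luke Homer Gerard Doug Kenny Hubert Angelo Shaun Lyle Matt Lynn Alfonso
Orlando Rex Carlton Ernesto Cameron Neal Pablo Lorenzo Omar Wilbur
Meehai Liam Noah Ethan Mason Logan Lucas Elijah Aiden Jackson Sebastian
Owen Gavin Wyatt Carter Connor Hunter Caleb Nolan Isaiah Landon
""".split()

LAST_CORE = """
Smith Johnson Williams Brown Jones Miller Davis Garcia Rodriguez Wilson
Martinez Anderson Taylor Thomas Hernandez Moore Martin Jackson Thompson
White Lopez Lee Gonzalez Harris Clark Lewis Robinson Walker Perez Hall
Young Allen Sanchez Wright King Scott Green Baker Adams Nelson Hill
Ramirez Campbell Mitchell Roberts Carter Phillips Evans Turner Torres
Parker Collins Edwards Stewart Flores Morris Nguyen Murphy Rivera Cook
Rogers Morgan Peterson Cooper Reed Bailey Bell Gomez Kelly Howard Ward
Cox Diaz Richardson Wood Watson Brooks Bennett Gray James Reyes Cruz
Hughes Price Myers Long Foster Sanders Ross Morales Powell Sullivan
Russell Ortiz Jenkins Gutierrez Perry Butler Barnes Fisher Henderson
Coleman Simmons Patterson Jordan Reynolds Hamilton Graham Kim Gonzales
Alexander Ramos Wallace Griffin West Cole Hayes Chavez Gibson Bryant
Ellis Stevens Murray Ford Marshall Owens McDonald Harrison Ruiz Kennedy
Wells Alvarez Woods Mendoza Castillo Olson Webb Washington Tucker Freeman
Burns Henry Vasquez Snyder Simpson Crawford Jimenez Porter Mason Shaw
Gordon Wagner Hunter Romero Hicks Dixon Hunt Palmer Robertson Black
Holmes Stone Meyer Boyd Mills Warren Fox Rose Rice Moreno Schmidt Patel
Ferguson Nichols Herrera Medina Ryan Fernandez Weaver Daniels Stephens
Gardner Payne Kelley Dunn Pierce Arnold Tran Spencer Peters Hawkins
Grant Hansen Castro Hoffman Hart Elliott Cunningham Knight Bradley
Carroll Hudson Duncan Armstrong Berry Andrews Johnston Ray Lane Riley
Carpenter Perkins Aguilar Silva Richards Willis Matthews Chapman Lawrence
Garza Vargas Watkins Wheeler Larson Carlson Harper George Greene Burke
Guzman Morrison Munoz Jacobs Obrien Lawson Franklin Lynch Bishop Carr
Salazar Austin Mendez Gilbert Jensen Williamson Montgomery Harvey Oliver
Howell Dean Hanson Weber Garrett Sims Burton Fuller Soto McCoy Welch
Chen Schultz Walters Reid Fields Walsh Little Fowler Bowman Davidson
May Day Schneider Gallagher Sandoval Barrett Bowers Norton Osborne Paul
Love Robles Salinas Yates Baldwin Blackwell Merritt Petersen Dodson
Atkins Ayala Ayers Barber Barker Barlow Barnett Barron Barry Bartlett
Barton Bass Bates Battle Bauer Baxter Beach Bean Beard Beasley Beck
Becker Benjamin Benson Bentley Benton Bernard Berger Best Bird Blair
Blake Blanchard Blankenship Blevins Bolton Bond Bonner Booker Boone
Booth Bowen Boyer Boyle Bradford Bradshaw Brady Branch Bray Brennan
Brewer Bridges Briggs Bright Britt Brock Bruce Bryan Buchanan Buck
Buckley Buckner Bullock Burch Burgess Burks Burnett Burris Burt Bush
Butts Byers Byrd Cabrera Cain Calderon Caldwell Calhoun Callahan Camacho
Cameron Cantrell Cantu Cardenas Carey Carney Carrillo Carson Carver Case
Casey Cash Cassidy Castaneda Cervantes Chambers Chan Chandler Chaney
Chang Charles Chase Cherry Christensen Christian Clarke Clay Clayton
Clements Cleveland Cline Cobb Cochran Coffey Cohen Cole Coley Conley
Conner Conrad Contreras Conway Cooke Cooley Copeland Cortez Cote Cotton
Craft Craig Crane Crosby Cross Cummings Curry Curtis Dale Dalton Daniel
Daugherty Davenport David Dawson Decker Dejesus Delacruz Delaney Deleon
Delgado Dennis Dillard Dillon Dominguez Donaldson Donovan Dorsey Dotson
Downs Doyle Drake Dudley Duffy Duke Dunlap Duran Durham Dyer Eaton
""".split()

NICKNAMES = {
    "William": ["Bill", "Billy", "Will", "Willy", "Liam"],
    "Robert": ["Bob", "Bobby", "Rob", "Robbie", "Bert"],
    "Richard": ["Rick", "Ricky", "Dick", "Rich", "Richie"],
    "Michael": ["Mike", "Mikey", "Mick", "Mickey"],
    "James": ["Jim", "Jimmy", "Jamie"],
    "John": ["Johnny", "Jon", "Jack"],
    "Joseph": ["Joe", "Joey"],
    "Thomas": ["Tom", "Tommy"],
    "Charles": ["Charlie", "Chuck", "Chas"],
    "Christopher": ["Chris", "Kit", "Topher"],
    "Daniel": ["Dan", "Danny"],
    "Matthew": ["Matt", "Matty"],
    "Anthony": ["Tony", "Ant"],
    "Donald": ["Don", "Donny"],
    "Steven": ["Steve", "Stevie"],
    "Edward": ["Ed", "Eddie", "Ted", "Ned", "Teddy"],
    "Kenneth": ["Ken", "Kenny"],
    "Andrew": ["Andy", "Drew"],
    "Joshua": ["Josh"],
    "Timothy": ["Tim", "Timmy"],
    "Nicholas": ["Nick", "Nicky"],
    "Alexander": ["Alex", "Sasha", "Xander", "Lex"],
    "Benjamin": ["Ben", "Benny", "Benji"],
    "Samuel": ["Sam", "Sammy"],
    "Gregory": ["Greg"],
    "Patrick": ["Pat", "Paddy"],
    "Lawrence": ["Larry"],
    "Jonathan": ["Jonny", "Nathan"],
    "Zachary": ["Zach", "Zack"],
    "Jacob": ["Jake"],
    "Nathaniel": ["Nate", "Nat"],
    "Theodore": ["Theo", "Teddy"],
    "Raymond": ["Ray"],
    "Gerald": ["Jerry", "Gerry"],
    "Ronald": ["Ron", "Ronnie"],
    "Peter": ["Pete"],
    "Frederick": ["Fred", "Freddy", "Freddie"],
    "Elizabeth": ["Liz", "Lizzy", "Beth", "Betsy", "Eliza", "Libby", "Betty"],
    "Margaret": ["Maggie", "Meg", "Peggy", "Marge", "Midge", "Greta"],
    "Katherine": ["Kate", "Katie", "Kathy", "Kitty", "Kat"],
    "Jennifer": ["Jen", "Jenny", "Jenna"],
    "Jessica": ["Jess", "Jessie"],
    "Patricia": ["Pat", "Patty", "Trish", "Tricia"],
    "Susan": ["Sue", "Susie", "Suzy"],
    "Deborah": ["Deb", "Debbie"],
    "Barbara": ["Barb", "Babs"],
    "Christina": ["Chris", "Christy", "Tina"],
    "Victoria": ["Vicky", "Tori"],
    "Rebecca": ["Becky", "Becca"],
    "Stephanie": ["Steph"],
    "Samantha": ["Sam", "Sammy"],
    "Alexandra": ["Alex", "Lexi", "Sandra", "Sasha"],
    "Kimberly": ["Kim"],
    "Cynthia": ["Cindy"],
    "Sandra": ["Sandy"],
    "Pamela": ["Pam"],
    "Dorothy": ["Dot", "Dottie"],
    "Florence": ["Flo", "Flossie"],
    "Josephine": ["Jo", "Josie"],
    "Eleanor": ["Ellie", "Nell", "Nora"],
    "Abigail": ["Abby", "Gail"],
    "Isabella": ["Bella", "Izzy"],
    "Gabriella": ["Gabby", "Ella"],
    "Angela": ["Angie"],
    "Amanda": ["Mandy"],
    "Melissa": ["Mel", "Missy"],
    "Michelle": ["Shelly"],
    "Natalie": ["Nat"],
    "Danielle": ["Dani"],
    "Veronica": ["Ronnie"],
    "Valentina": ["Val", "Tina"],
}

VOWELS = set("aeiou")


def variants(name: str) -> list[str]:
    """Common informal-spelling variants: a dropped interior vowel (the way
    'Bill' is mistyped 'Bll'), y/ie ending swaps, an undoubled consonant."""
    out = []
    for i, ch in enumerate(name[1:-1], start=1):
        if ch.lower() in VOWELS:
            v = name[:i] + name[i + 1:]
            if len(v) >= 3:
                out.append(v)
    if name.endswith("y"):
        out.append(name[:-1] + "ie")
    elif name.endswith("ie"):
        out.append(name[:-2] + "y")
    for i in range(1, len(name) - 1):
        if name[i] == name[i + 1] and name[i].lower() not in VOWELS:
            out.append(name[:i] + name[i + 1:])
            break
    return out


def expand_first(core: list[str], want: int) -> list[str]:
    out: dict[str, None] = {}
    for n in core:
        out[n] = None
        for nick in NICKNAMES.get(n, []):
            out[nick] = None
    base = list(out)
    for n in base:
        if len(out) >= want:
            break
        for v in variants(n):
            out.setdefault(v, None)
            if len(out) >= want:
                break
    return list(out)


def expand_last(core: list[str], firsts: list[str], want: int) -> list[str]:
    out: dict[str, None] = {n: None for n in core}
    for f in firsts:  # patronymic derivations
        if len(out) >= want:
            break
        if f.endswith(("s", "x", "z")):
            continue
        out[f + "son"] = None
    for n in core:
        if len(out) >= want:
            break
        for prefix in ("Mc", "O'"):
            out[prefix + n] = None
            if len(out) >= want:
                break
    return list(out)


def main() -> None:
    dest = Path(__file__).resolve().parents[1] / "src/p2pwatch/resources/names"
    dest.mkdir(parents=True, exist_ok=True)
    female = expand_first(FEMALE_CORE, 1100)
    male = expand_first(MALE_CORE, 1100)
    male.append("Bll")  # canonical misspelling example
    last = expand_last(LAST_CORE, MALE_CORE, 1100)
    for fname, entries in [
        ("female_first.txt", female),
        ("male_first.txt", male),
        ("last.txt", last),
    ]:
        uniq = sorted(dict.fromkeys(entries))
        (dest / fname).write_text("\n".join(uniq) + "\n", encoding="utf-8")
        print(fname, len(uniq))


if __name__ == "__main__":
    main()
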